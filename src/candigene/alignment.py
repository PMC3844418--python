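"""Smith-Waterman local alignment with affine gaps.

The aligner scores pairs of domain subsequences for the seeded
domain-profiling engine. Scoring is controlled by a :class:`ScoringScheme`
(substitution matrix + affine gap penalties); a gap of length L costs
``gap_open + L * gap_extend``, i.e. the open penalty is charged together
with the extend penalty at the first gap position. Defaults follow common
protein-search practice: BLOSUM62 with gap open 11, extend 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

from Bio.Align import substitution_matrices

UNKNOWN_RESIDUE = "X"


def _matrix_to_dict(arr) -> dict[str, dict[str, float]]:
    alphabet = list(arr.alphabet)
    return {
        a: {b: float(arr[a, b]) for b in alphabet}
        for a in alphabet
    }


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (penalties are >= 0)."""

    name: str
    matrix: Mapping[str, Mapping[str, float]]
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        for a, row in self.matrix.items():
            for b, s in row.items():
                if abs(s - self.matrix[b][a]) > 1e-9:
                    raise ValueError(f"matrix not symmetric at ({a},{b})")

    @property
    def alphabet(self) -> set[str]:
        return set(self.matrix)

    def score(self, a: str, b: str) -> float:
        """Substitution score; residues outside the alphabet score as X."""
        row = self.matrix.get(a) or self.matrix.get(UNKNOWN_RESIDUE)
        if row is None:
            raise KeyError(f"residue {a!r} not in matrix and no X column")
        s = row.get(b)
        if s is None:
            s = row.get(UNKNOWN_RESIDUE)
            if s is None:
                raise KeyError(f"residue {b!r} not in matrix and no X column")
        return s

    @classmethod
    def from_preset(
        cls, name: str = "BLOSUM62", gap_open: float = 11, gap_extend: float = 1
    ) -> "ScoringScheme":
        """A named substitution matrix shipped with Biopython (offline)."""
        arr = substitution_matrices.load(name)
        return cls(name, _matrix_to_dict(arr), gap_open, gap_extend)

    @classmethod
    def from_file(
        cls, path: Union[str, Path], gap_open: float = 11, gap_extend: float = 1
    ) -> "ScoringScheme":
        """Read an NCBI-format substitution matrix file."""
        with open(path) as fh:
            arr = substitution_matrices.read(fh)
        return cls(Path(path).name, _matrix_to_dict(arr), gap_open, gap_extend)

    @classmethod
    def simple(
        cls,
        alphabet: str,
        match: float,
        mismatch: float,
        gap_open: float,
        gap_extend: float,
        name: str = "simple",
    ) -> "ScoringScheme":
        """A toy match/mismatch scheme over an explicit alphabet."""
        matrix = {
            a: {b: (match if a == b else mismatch) for b in alphabet} for a in alphabet
        }
        return cls(name, matrix, gap_open, gap_extend)


DEFAULT_SCHEME = None  # lazily built; see default_scheme()


def default_scheme() -> ScoringScheme:
    global DEFAULT_SCHEME
    if DEFAULT_SCHEME is None:
        DEFAULT_SCHEME = ScoringScheme.from_preset("BLOSUM62", 11, 1)
    return DEFAULT_SCHEME


def smith_waterman(seq_a: str, seq_b: str, scheme: ScoringScheme) -> float:
    """Optimal local alignment score (>= 0) by affine-gap dynamic programming.

    Empty input means no alignment and scores 0. The score is symmetric in
    its arguments.
    """
    if not seq_a or not seq_b:
        return 0.0
    gap1 = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    matrix = scheme.matrix
    unknown = matrix.get(UNKNOWN_RESIDUE)

    n = len(seq_b)
    neg = float("-inf")
    h_prev = [0.0] * (n + 1)  # H for previous row
    e_prev = [neg] * (n + 1)  # E: alignment ending with a gap in seq_b (vertical)
    best = 0.0
    for ca in seq_a:
        row = matrix.get(ca, unknown)
        if row is None:
            raise KeyError(f"residue {ca!r} not in matrix and no X column")
        h_cur = [0.0] * (n + 1)
        e_cur = [neg] * (n + 1)
        f = neg  # F: alignment ending with a gap in seq_a (horizontal)
        for j in range(1, n + 1):
            cb = seq_b[j - 1]
            s = row.get(cb)
            if s is None:
                s = row.get(UNKNOWN_RESIDUE)
                if s is None:
                    raise KeyError(f"residue {cb!r} not in matrix and no X column")
            e = max(h_prev[j] - gap1, e_prev[j] - ge)
            f = max(h_cur[j - 1] - gap1, f - ge)
            h = h_prev[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            e_cur[j] = e
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return best
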