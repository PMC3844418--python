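"""Locus construction and GWAS SNP-to-gene search spaces.

A locus is a genomic interval together with its member genes. Intervals may
be specified by a marker pair, a central marker plus a width, or explicit
coordinates. SNPs are expanded to gene sets by two rules:

* *adjacent* — the gene(s) containing the SNP plus, for each strand and each
  side of the SNP, the nearest non-containing gene (at most 4 flankers);
* *bystander* — every gene overlapping a fixed window (default 1 Mbp)
  centered on the SNP.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .bundle import ReferenceBundle
from .models import Gene, Marker

logger = logging.getLogger("candigene")

DEFAULT_WINDOW_BP = 1_000_000

MODE_ADJACENT = "adjacent"
MODE_BYSTANDER = "bystander"
MODE_INTERVALS = "intervals"


class LocusError(ValueError):
    """Invalid locus specification or unmappable input."""


@dataclass(frozen=True)
class IntervalSpec:
    """How a genomic interval was specified by the user."""

    mode: str  # marker_pair | center_width | explicit
    locus_id: Optional[str] = None
    marker_start_id: Optional[str] = None
    marker_end_id: Optional[str] = None
    center_marker_id: Optional[str] = None
    width_bp: Optional[int] = None
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None

    @staticmethod
    def marker_pair(a: str, b: str, locus_id: Optional[str] = None) -> "IntervalSpec":
        return IntervalSpec("marker_pair", locus_id, marker_start_id=a, marker_end_id=b)

    @staticmethod
    def center_width(marker: str, width_bp: int, locus_id: Optional[str] = None) -> "IntervalSpec":
        return IntervalSpec("center_width", locus_id, center_marker_id=marker, width_bp=width_bp)

    @staticmethod
    def explicit(chrom: str, start: int, end: int, locus_id: Optional[str] = None) -> "IntervalSpec":
        return IntervalSpec("explicit", locus_id, chrom=chrom, start=start, end=end)


@dataclass(frozen=True)
class Locus:
    """A genomic interval with its member genes, in discovery order by start."""

    locus_id: str
    chrom: str
    start: int
    end: int
    gene_ids: tuple[str, ...]
    provenance: str = ""


@dataclass
class SearchSpace:
    """A collection of loci with gene <-> locus multi-membership retained."""

    loci: list[Locus]
    gene_to_loci: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_to_loci:
            mapping: dict[str, set[str]] = {}
            for locus in self.loci:
                for gid in locus.gene_ids:
                    mapping.setdefault(gid, set()).add(locus.locus_id)
            self.gene_to_loci = mapping

    @property
    def universe_n(self) -> int:
        """Distinct genes across all loci."""
        return len(self.gene_to_loci)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_loci)

    def loci_of(self, gene_id: str) -> set[str]:
        return self.gene_to_loci.get(gene_id, set())


# -------------------------------------------------------------- resolution

def _get_marker(bundle: ReferenceBundle, marker_id: str) -> Marker:
    m = bundle.markers.get(marker_id)
    if m is None:
        raise LocusError(f"unknown marker_id {marker_id!r}")
    return m


def resolve_interval(spec: IntervalSpec, bundle: ReferenceBundle) -> tuple[str, int, int]:
    """Resolve an interval specification to (chrom, start, end), half-open."""
    if spec.mode == "marker_pair":
        a = _get_marker(bundle, spec.marker_start_id)
        b = _get_marker(bundle, spec.marker_end_id)
        if a.chrom != b.chrom:
            raise LocusError(
                f"markers {a.marker_id}/{b.marker_id} lie on different chromosomes"
            )
        lo, hi = sorted((a.pos, b.pos))
        return a.chrom, lo, hi + 1
    if spec.mode == "center_width":
        if spec.width_bp is None or spec.width_bp <= 0:
            raise LocusError(f"width_bp must be positive, got {spec.width_bp}")
        m = _get_marker(bundle, spec.center_marker_id)
        half = spec.width_bp // 2
        return m.chrom, max(0, m.pos - half), m.pos + half
    if spec.mode == "explicit":
        if spec.start is None or spec.end is None or spec.start >= spec.end:
            raise LocusError(f"explicit interval requires start < end, got {spec}")
        return spec.chrom, spec.start, spec.end
    raise LocusError(f"unknown interval mode {spec.mode!r}")


def build_locus(spec: IntervalSpec, bundle: ReferenceBundle, locus_id: str) -> Locus:
    """Materialize a locus: resolved interval plus its member genes."""
    chrom, start, end = resolve_interval(spec, bundle)
    genes = bundle.genes_in_interval(chrom, start, end)
    if not genes:
        logger.warning("locus %s [%s:%d-%d) contains no genes", locus_id, chrom, start, end)
    return Locus(
        locus_id=locus_id,
        chrom=chrom,
        start=start,
        end=end,
        gene_ids=tuple(g.gene_id for g in genes),
        provenance=f"{spec.mode}",
    )


# ------------------------------------------------------------ SNP mappings

def map_snp_adjacent(snp: Marker, bundle: ReferenceBundle) -> list[Gene]:
    """Genes containing the SNP plus the nearest flanking gene per strand and
    side (at most 4 flankers), sorted by (start, gene_id).

    Distance is measured from the SNP position to the nearest gene edge, so
    the rule is strand-symmetric; ties break on smaller start then gene_id.
    """
    if snp.kind != "snp":
        raise LocusError(f"marker {snp.marker_id} is not a SNP")
    glist = bundle.chrom_genes(snp.chrom)
    if not glist:
        logger.warning("SNP %s: no genes on chromosome %r", snp.marker_id, snp.chrom)
        return []
    pos = snp.pos
    out: dict[str, Gene] = {}
    for g in glist:
        if g.contains(pos):
            out[g.gene_id] = g

    # scan outward from the insertion point per strand and side
    starts = [g.start for g in glist]
    pivot = bisect_left(starts, pos)
    for strand in ("+", "-"):
        # left side: genes entirely before pos (end <= pos)
        # gene ends are not monotone in start, so scan every gene left of the
        # pivot; chromosome lists are short enough that this stays cheap
        best_left = None
        for i in range(min(pivot, len(glist) - 1), -1, -1):
            g = glist[i]
            if g.strand != strand or g.end > pos:
                continue
            key = (pos - g.end, g.start, g.gene_id)
            if best_left is None or key < best_left[0]:
                best_left = (key, g)
        if best_left is not None:
            out.setdefault(best_left[1].gene_id, best_left[1])
        # right side: genes entirely after pos (start > pos)
        best_right = None
        for i in range(pivot, len(glist)):
            g = glist[i]
            if g.strand != strand or g.start <= pos:
                continue
            key = (g.start - pos, g.start, g.gene_id)
            if best_right is None or key < best_right[0]:
                best_right = (key, g)
                break  # sorted by start: the first qualifying gene is nearest
        if best_right is not None:
            out.setdefault(best_right[1].gene_id, best_right[1])

    return sorted(out.values(), key=lambda g: (g.start, g.gene_id))


def map_snp_bystander(
    snp: Marker,
    window_bp: int,
    bundle: ReferenceBundle,
    locus_id: Optional[str] = None,
) -> Locus:
    """All genes within a window of ``window_bp`` centered on the SNP."""
    if window_bp <= 0:
        raise LocusError(f"window_bp must be positive, got {window_bp}")
    spec = IntervalSpec.center_width(snp.marker_id, window_bp)
    # the SNP may be an ad-hoc marker not registered in the bundle
    if snp.marker_id not in bundle.markers:
        half = window_bp // 2
        spec = IntervalSpec.explicit(snp.chrom, max(0, snp.pos - half), snp.pos + half)
    return build_locus(spec, bundle, locus_id or snp.marker_id)


def build_search_space(
    inputs: Sequence[Union[Marker, IntervalSpec]],
    mode: str,
    bundle: ReferenceBundle,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> SearchSpace:
    """One locus per input marker/spec; multi-membership of genes retained.

    ``adjacent`` mode spans each locus from the first to the last mapped
    gene; inputs mapping to zero genes are dropped with a warning; if every
    input is unmappable the search space is undefined and an error is raised.
    """
    if not inputs:
        raise LocusError("no loci given")
    loci: list[Locus] = []
    if mode == MODE_ADJACENT:
        for snp in inputs:
            genes = map_snp_adjacent(snp, bundle)
            if not genes:
                logger.warning("SNP %s maps to no genes; dropped", snp.marker_id)
                continue
            loci.append(
                Locus(
                    locus_id=snp.marker_id,
                    chrom=snp.chrom,
                    start=min(g.start for g in genes),
                    end=max(g.end for g in genes),
                    gene_ids=tuple(
                        g.gene_id for g in sorted(genes, key=lambda g: (g.start, g.gene_id))
                    ),
                    provenance=f"adjacent:{snp.marker_id}",
                )
            )
    elif mode == MODE_BYSTANDER:
        for snp in inputs:
            locus = map_snp_bystander(snp, window_bp, bundle)
            locus = Locus(
                locus.locus_id, locus.chrom, locus.start, locus.end, locus.gene_ids,
                provenance=f"bystander:{snp.marker_id}:{window_bp}",
            )
            if not locus.gene_ids:
                logger.warning("SNP %s: empty bystander locus; dropped", snp.marker_id)
                continue
            loci.append(locus)
    elif mode == MODE_INTERVALS:
        for i, spec in enumerate(inputs, start=1):
            locus_id = spec.locus_id or f"locus{i:03d}"
            locus = build_locus(spec, bundle, locus_id)
            if not locus.gene_ids:
                logger.warning("interval locus %s is gene-free; dropped", locus_id)
                continue
            loci.append(locus)
    else:
        raise LocusError(f"unknown search-space mode {mode!r}")

    if not loci:
        raise LocusError("every input was unmappable; search space is empty")
    seen = set()
    for locus in loci:
        if locus.locus_id in seen:
            raise LocusError(f"duplicate locus_id {locus.locus_id}")
        seen.add(locus.locus_id)
    return SearchSpace(loci=loci)


# --------------------------------------------------------------- batch input

def parse_snp_lines(lines: Iterable[str], bundle: ReferenceBundle) -> list[Marker]:
    """Parse pasted/batched SNP input: one marker_id or ``chrom:pos`` per line.

    ``chrom:pos`` entries become ad-hoc SNP markers named after themselves.
    '#' comments and blank lines are skipped.
    """
    markers = []
    for lineno, raw in enumerate(lines, start=1):
        tok = raw.strip()
        if not tok or tok.startswith("#"):
            continue
        if tok in bundle.markers:
            m = bundle.markers[tok]
            if m.kind != "snp":
                raise LocusError(f"line {lineno}: marker {tok} is not a SNP")
            markers.append(m)
        elif ":" in tok:
            chrom, _, pos = tok.partition(":")
            try:
                markers.append(Marker(tok, "snp", chrom, int(pos.replace(",", ""))))
            except ValueError as exc:
                raise LocusError(f"line {lineno}: bad chrom:pos entry {tok!r}") from exc
        else:
            raise LocusError(f"line {lineno}: unknown marker {tok!r}")
    return markers


def parse_interval_lines(lines: Iterable[str], bundle: ReferenceBundle) -> list[IntervalSpec]:
    """Parse batched interval input, one locus per line.

    Accepted TSV layouts: ``locus_id chrom start end`` (explicit),
    ``locus_id marker_a marker_b`` (marker pair), or
    ``locus_id center_marker width`` (center+width; width must be numeric and
    the second column a known marker).
    """
    specs = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if len(f) == 4:
            try:
                specs.append(IntervalSpec.explicit(f[1], int(f[2]), int(f[3]), locus_id=f[0]))
            except ValueError as exc:
                raise LocusError(f"line {lineno}: bad explicit interval") from exc
        elif len(f) == 3:
            if f[1] in bundle.markers and f[2].isdigit():
                specs.append(IntervalSpec.center_width(f[1], int(f[2]), locus_id=f[0]))
            else:
                specs.append(IntervalSpec.marker_pair(f[1], f[2], locus_id=f[0]))
        else:
            raise LocusError(f"line {lineno}: expected 3 or 4 columns, got {len(f)}")
    return specs


# ------------------------------------------------------------------ export

def space_to_bed(space: SearchSpace) -> str:
    """BED rendering of the loci of a search space."""
    lines = []
    for locus in sorted(space.loci, key=lambda l: (l.chrom, l.start, l.locus_id)):
        lines.append(f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}")
    return "\n".join(lines) + "\n"


def space_gene_table(space: SearchSpace, bundle: ReferenceBundle) -> str:
    """TSV of (gene_id, symbol, locus_ids) across the search space."""
    lines = ["gene_id\tsymbol\tlocus_ids"]
    for gid in sorted(space.gene_to_loci):
        sym = bundle.genes[gid].symbol if gid in bundle.genes else gid
        lines.append(f"{gid}\t{sym}\t{','.join(sorted(space.gene_to_loci[gid]))}")
    return "\n".join(lines) + "\n"
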