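"""File readers and writers for the reference formats.

Formats (all plain text):

* genes — BED6 (+ optional 7th column symbol); name column = gene_id.
* gene sets — GMT: ``set_id <TAB> source_db[:name] <TAB> member ...``.
* edges — 3-column TSV ``gene_a  gene_b  source``; header optional.
* domains — 5-column TSV ``protein_id family_id ali_start ali_end bit_score``.
* proteins — FASTA; header token 1 = protein_id, optional ``gene=<id>`` tag.
* markers — 4-column TSV ``marker_id kind chrom pos``.
* phenotypes — TSV ``phenotype_id  name  gene,gene,...``.

Malformed lines are fatal with the file name and line number; unresolvable
cross-references are dropped with warnings at bundle assembly time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Union

from Bio import SeqIO

from .bundle import ReferenceBundle, ReferenceError
from .models import (
    DomainHit,
    Gene,
    GeneSet,
    InteractionEdge,
    Marker,
    PhenotypeRecord,
    ProteinRecord,
)

PathLike = Union[str, Path]


class FormatError(ReferenceError):
    """A malformed line in an input file (fatal, carries file:line)."""


def _rows(path: PathLike) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping blanks/comments."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _die(path: PathLike, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


# ------------------------------------------------------------------- readers

def read_genes_bed(path: PathLike) -> list[Gene]:
    genes = []
    for lineno, f in _rows(path):
        if len(f) < 6:
            _die(path, lineno, f"expected >= 6 BED columns, got {len(f)}")
        chrom, start, end, gene_id, _score, strand = f[:6]
        symbol = f[6] if len(f) >= 7 and f[6] else gene_id
        try:
            genes.append(Gene(gene_id, symbol, chrom, int(start), int(end), strand))
        except ValueError as exc:
            _die(path, lineno, str(exc))
    return genes


def read_gmt(path: PathLike) -> list[GeneSet]:
    sets = []
    for lineno, f in _rows(path):
        if len(f) < 3:
            _die(path, lineno, "GMT line needs set_id, description and >= 1 member")
        set_id, desc = f[0], f[1]
        # description field carries "source_db" or "source_db:set name"
        source, _, name = desc.partition(":")
        members = frozenset(m for m in f[2:] if m)
        if not members:
            _die(path, lineno, "GMT line has no members")
        sets.append(GeneSet(set_id, name or set_id, source or "custom", members))
    return sets


def read_edges(path: PathLike) -> list[tuple[str, str, str]]:
    """Raw (gene_a, gene_b, source) triples; canonicalized at bundle assembly
    so that self edges can be dropped with a warning there."""
    edges = []
    for lineno, f in _rows(path):
        if f[0].lower() in ("gene_a", "genea") and lineno == 1:
            continue  # optional header
        if len(f) < 2:
            _die(path, lineno, "edge line needs gene_a and gene_b")
        edges.append((f[0], f[1], f[2] if len(f) > 2 else ""))
    return edges


def read_domains(path: PathLike) -> list[DomainHit]:
    hits = []
    for lineno, f in _rows(path):
        if f[0].lower() == "protein_id" and lineno == 1:
            continue
        if len(f) < 4:
            _die(path, lineno, "domain line needs protein_id, family_id, ali_start, ali_end")
        try:
            score = float(f[4]) if len(f) > 4 and f[4] not in ("", "-") else None
            hits.append(DomainHit(f[0], f[1], int(f[2]), int(f[3]), score))
        except ValueError as exc:
            _die(path, lineno, str(exc))
    return hits


def read_proteins_fasta(path: PathLike) -> list[ProteinRecord]:
    prots = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = ""
        for tok in rec.description.split()[1:]:
            if tok.startswith("gene="):
                gene_id = tok[len("gene="):]
                break
        prots.append(ProteinRecord(rec.id, gene_id, str(rec.seq).upper()))
    return prots


def read_markers(path: PathLike) -> list[Marker]:
    markers = []
    for lineno, f in _rows(path):
        if f[0].lower() == "marker_id" and lineno == 1:
            continue
        if len(f) < 4:
            _die(path, lineno, "marker line needs marker_id, kind, chrom, pos")
        try:
            markers.append(Marker(f[0], f[1], f[2], int(f[3])))
        except ValueError as exc:
            _die(path, lineno, str(exc))
    return markers


def read_phenotypes(path: PathLike) -> list[PhenotypeRecord]:
    phens = []
    for lineno, f in _rows(path):
        if f[0].lower() == "phenotype_id" and lineno == 1:
            continue
        if len(f) < 2:
            _die(path, lineno, "phenotype line needs phenotype_id and name")
        seeds = frozenset(
            tok for tok in (f[2].split(",") if len(f) > 2 and f[2] else []) if tok
        )
        phens.append(PhenotypeRecord(f[0], f[1], seeds))
    return phens


#: role name -> reader
_READERS = {
    "genes": read_genes_bed,
    "gene_sets": read_gmt,
    "edges": read_edges,
    "domains": read_domains,
    "proteins": read_proteins_fasta,
    "markers": read_markers,
    "phenotypes": read_phenotypes,
}

#: conventional file names used by write_bundle / case directories
STANDARD_NAMES = {
    "genes": "genes.bed",
    "gene_sets": "pathways.gmt",
    "edges": "ppi_edges.tsv",
    "domains": "domains.tsv",
    "proteins": "proteins.fasta",
    "markers": "markers.tsv",
    "phenotypes": "phenotypes.tsv",
}


def load_reference(paths: Mapping[str, PathLike]) -> ReferenceBundle:
    """Read, validate and index a reference bundle from files.

    ``paths`` maps roles (``genes`` required; ``gene_sets``, ``edges``,
    ``domains``, ``proteins``, ``markers``, ``phenotypes`` optional) to file
    paths. Malformed lines are fatal; unresolved cross-references are dropped
    with warnings recorded on the bundle.
    """
    unknown = set(paths) - set(_READERS)
    if unknown:
        raise ReferenceError(f"unknown reference roles: {sorted(unknown)}")
    if "genes" not in paths:
        raise ReferenceError("a 'genes' file is required")
    records: dict[str, list] = {}
    for role, path in paths.items():
        if not Path(path).exists():
            raise ReferenceError(f"{role} file not found: {path}")
        records[role] = _READERS[role](path)
    return ReferenceBundle(
        genes=records["genes"],
        proteins=records.get("proteins", ()),
        domain_hits=records.get("domains", ()),
        gene_sets=records.get("gene_sets", ()),
        edges=records.get("edges", ()),
        markers=records.get("markers", ()),
        phenotypes=records.get("phenotypes", ()),
    )


def discover_reference(directory: PathLike) -> dict[str, Path]:
    """Map roles to the standard file names present in a case directory."""
    directory = Path(directory)
    return {
        role: directory / fname
        for role, fname in STANDARD_NAMES.items()
        if (directory / fname).exists()
    }


# ------------------------------------------------------------------- writers

def write_genes_bed(genes: Iterable[Gene], path: PathLike) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.symbol}\n")


def write_gmt(gene_sets: Iterable[GeneSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sorted(gene_sets, key=lambda s: (s.source_db, s.set_id)):
            desc = f"{gs.source_db}:{gs.name}"
            fh.write("\t".join([gs.set_id, desc, *sorted(gs.members)]) + "\n")


def write_edges(edges: Iterable[InteractionEdge], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b)):
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.source}\n")


def write_domains(hits: Iterable[DomainHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily_id\tali_start\tali_end\tbit_score\n")
        for h in sorted(hits, key=lambda h: (h.protein_id, h.ali_start, h.family_id)):
            score = "-" if h.bit_score is None else f"{h.bit_score:g}"
            fh.write(f"{h.protein_id}\t{h.family_id}\t{h.ali_start}\t{h.ali_end}\t{score}\n")


def write_proteins_fasta(proteins: Iterable[ProteinRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in sorted(proteins, key=lambda p: p.protein_id):
            fh.write(f">{p.protein_id} gene={p.gene_id}\n")
            for i in range(0, len(p.residues), 60):
                fh.write(p.residues[i : i + 60] + "\n")


def write_markers(markers: Iterable[Marker], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tkind\tchrom\tpos\n")
        for m in sorted(markers, key=lambda m: m.marker_id):
            fh.write(f"{m.marker_id}\t{m.kind}\t{m.chrom}\t{m.pos}\n")


def write_phenotypes(phenotypes: Iterable[PhenotypeRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("phenotype_id\tname\tseed_genes\n")
        for ph in sorted(phenotypes, key=lambda p: p.phenotype_id):
            fh.write(f"{ph.phenotype_id}\t{ph.name}\t{','.join(sorted(ph.seed_genes))}\n")


def write_bundle(bundle: ReferenceBundle, directory: PathLike) -> dict[str, Path]:
    """Write every populated component of a bundle under standard names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _put(role: str, writer, items) -> None:
        items = list(items)
        if role == "genes" or items:
            p = directory / STANDARD_NAMES[role]
            writer(items, p)
            paths[role] = p

    _put("genes", write_genes_bed, bundle.genes.values())
    _put("gene_sets", write_gmt, bundle.gene_sets.values())
    _put("edges", write_edges, bundle.edge_records)
    _put("domains", write_domains, bundle.domain_hits)
    _put("proteins", write_proteins_fasta, bundle.proteins.values())
    _put("markers", write_markers, bundle.markers.values())
    _put("phenotypes", write_phenotypes, bundle.phenotypes.values())
    return paths
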