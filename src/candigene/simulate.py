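"""Deterministic synthetic reference bundles and planted prediction cases.

The generator emits a complete toy reference — genome annotation, pathways,
interaction edges, proteins with domain assignments, markers, phenotypes —
standing in for the public resources a production deployment would ingest,
so every engine is testable offline. Domain-family identity is carried by a
per-family consensus sequence reproduced on every instance with ~10% point
noise, so same-family instances align with high normalized similarity while
cross-family instances do not.

:func:`plant_case` then buries a true module (a pathway, a domain family or
an interaction clique) across several well-separated regions, designates
out-of-region members as known disease genes (seeds), and emits one SNP
inside each in-region member plus decoy SNPs elsewhere — the classic
artificial-locus benchmark design. The truth table records everything.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .bundle import ReferenceBundle, ReferenceError
from .io import write_bundle
from .models import (
    DomainHit,
    Gene,
    GeneSet,
    InteractionEdge,
    Marker,
    PhenotypeRecord,
    ProteinRecord,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

PLANTED_SET_ID = "PLANTED"
PLANTED_FAMILY_ID = "FAMPLANT"
PLANTED_SOURCE = "planted"


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic reference generator.

    Defaults describe the standard benchmark genome: 2 chromosomes of 100
    genes (10-100 kb long, 0.3-0.7 Mb apart, so a 1 Mbp window holds ~2
    genes), 30 pathways of 5-15 genes, a 50-family domain vocabulary with
    1-3 domains per gene, and 150 interaction edges.
    """

    rng_seed: int = 0
    n_chrom: int = 2
    genes_per_chrom: int = 100
    gene_len_range: tuple[int, int] = (10_000, 100_000)
    intergap_range: tuple[int, int] = (300_000, 700_000)
    strand_prob: float = 0.5
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (5, 15)
    pathway_source: str = "toypath"
    domain_vocab_size: int = 50
    domains_per_gene_range: tuple[int, int] = (1, 3)
    ppi_edge_count: int = 150
    protein_len_per_domain: int = 40
    domain_noise: float = 0.10
    n_markers: int = 20
    n_phenotypes: int = 2
    make_proteins: bool = True

    def validate(self) -> None:
        for lo, hi in (
            self.gene_len_range,
            self.intergap_range,
            self.pathway_size_range,
            self.domains_per_gene_range,
        ):
            if lo > hi or lo <= 0:
                raise ReferenceError(f"invalid range ({lo}, {hi})")
        if not (0 <= self.strand_prob <= 1) or not (0 <= self.domain_noise <= 1):
            raise ReferenceError("probabilities must lie in [0, 1]")
        n_genes = self.n_chrom * self.genes_per_chrom
        if self.n_pathways > 0 and self.pathway_size_range[1] > n_genes:
            raise ReferenceError(
                f"pathway size up to {self.pathway_size_range[1]} infeasible "
                f"with {n_genes} genes"
            )
        if self.make_proteins and self.domains_per_gene_range[1] > self.domain_vocab_size:
            raise ReferenceError("domains per gene cannot exceed the vocabulary size")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted case."""

    module_kind: str  # pathway | domain | ppi
    planted_id: str
    disease_gene_ids: tuple[str, ...]
    seed_gene_ids: tuple[str, ...]
    snp_markers: tuple[str, ...]  # truth SNPs first, then decoys
    decoy_summary: str = ""


def _mutated_consensus(consensus: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    arr = consensus.copy()
    mask = rng.random(arr.size) < noise
    n_mut = int(mask.sum())
    if n_mut:
        arr[mask] = rng.integers(0, AMINO_ACIDS.size, n_mut)
    return arr


def simulate_reference(
    params: SimulationParams,
    out_dir: Optional[Union[str, Path]] = None,
) -> ReferenceBundle:
    """Generate a reference bundle; optionally write it to ``out_dir``.

    Fully reproducible: identical params (including rng_seed) give an
    identical bundle and byte-identical files.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)

    genes: list[Gene] = []
    for c in range(1, params.n_chrom + 1):
        m = params.genes_per_chrom
        gaps = rng.integers(params.intergap_range[0], params.intergap_range[1] + 1, m)
        lens = rng.integers(params.gene_len_range[0], params.gene_len_range[1] + 1, m)
        strands = rng.random(m) < params.strand_prob
        starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lens)[:-1]))
        for i in range(m):
            gid = f"G{c:02d}{i + 1:04d}"
            genes.append(
                Gene(
                    gene_id=gid,
                    symbol=gid,
                    chrom=f"chr{c}",
                    start=int(starts[i]),
                    end=int(starts[i] + lens[i]),
                    strand="+" if strands[i] else "-",
                )
            )
    gene_ids = [g.gene_id for g in genes]

    gene_sets = []
    if params.n_pathways:
        sizes = rng.integers(
            params.pathway_size_range[0], params.pathway_size_range[1] + 1, params.n_pathways
        )
        for j in range(params.n_pathways):
            members = rng.choice(len(gene_ids), size=int(sizes[j]), replace=False)
            gene_sets.append(
                GeneSet(
                    set_id=f"PW{j + 1:03d}",
                    name=f"toy pathway {j + 1}",
                    source_db=params.pathway_source,
                    members=frozenset(gene_ids[i] for i in members),
                )
            )

    edges: list[InteractionEdge] = []
    seen = set()
    while len(edges) < params.ppi_edge_count:
        i, j = rng.integers(0, len(gene_ids), 2)
        if i == j:
            continue
        e = InteractionEdge.make(gene_ids[int(i)], gene_ids[int(j)], "toyppi")
        if (e.gene_a, e.gene_b) in seen:
            continue
        seen.add((e.gene_a, e.gene_b))
        edges.append(e)

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    if params.make_proteins:
        L = params.protein_len_per_domain
        vocab = [f"FAM{v + 1:03d}" for v in range(params.domain_vocab_size)]
        consensus = {
            fam: rng.integers(0, AMINO_ACIDS.size, L) for fam in vocab
        }
        d_lo, d_hi = params.domains_per_gene_range
        for g in genes:
            d = int(rng.integers(d_lo, d_hi + 1))
            fams = rng.choice(params.domain_vocab_size, size=d, replace=False)
            chunks = []
            pid = f"{g.gene_id}_P1"
            for slot, v in enumerate(fams):
                fam = vocab[int(v)]
                chunks.append(_mutated_consensus(consensus[fam], params.domain_noise, rng))
                hits.append(DomainHit(pid, fam, slot * L, (slot + 1) * L, 100.0))
            residues = "".join(AMINO_ACIDS[np.concatenate(chunks)])
            proteins.append(ProteinRecord(pid, g.gene_id, residues))

    markers: list[Marker] = []
    if params.n_markers:
        chrom_span = {g.chrom: 0 for g in genes}
        for g in genes:
            chrom_span[g.chrom] = max(chrom_span[g.chrom], g.end)
        chroms = sorted(chrom_span)
        for t in range(params.n_markers):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, chrom_span[chrom]))
            markers.append(Marker(f"sts{t + 1:04d}", "sts", chrom, pos))

    phenotypes: list[PhenotypeRecord] = []
    for t in range(params.n_phenotypes):
        k = int(rng.integers(2, 5))
        picks = rng.choice(len(gene_ids), size=k, replace=False)
        phenotypes.append(
            PhenotypeRecord(
                f"PH{t + 1:03d}",
                f"synthetic phenotype {t + 1}",
                frozenset(gene_ids[i] for i in picks),
            )
        )

    bundle = ReferenceBundle(
        genes=genes,
        proteins=proteins,
        domain_hits=hits,
        gene_sets=gene_sets,
        edges=edges,
        markers=markers,
        phenotypes=phenotypes,
    )
    if bundle.load_warnings:
        raise ReferenceError(
            f"generator produced an inconsistent bundle: {bundle.load_warnings[:3]}"
        )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
        _write_params(params, Path(out_dir) / "params.txt")
    return bundle


def _write_params(params: SimulationParams, path: Path) -> None:
    with open(path, "w") as fh:
        for key, value in asdict(params).items():
            if isinstance(value, tuple):
                value = f"{value[0]},{value[1]}"
            fh.write(f"{key} = {value}\n")


# ---------------------------------------------------------------- planting

def _pick_separated(
    order: Sequence[int],
    genes: Sequence[Gene],
    count: int,
    min_separation: int,
    taken: Sequence[int] = (),
) -> list[int]:
    """Greedily pick gene indices at least ``min_separation`` index positions
    apart (per chromosome) from each other and from ``taken``."""
    chosen: list[int] = []
    blocked = list(taken)
    for idx in order:
        g = genes[idx]
        ok = all(
            genes[b].chrom != g.chrom or abs(b - idx) >= min_separation for b in blocked
        )
        if ok:
            chosen.append(idx)
            blocked.append(idx)
            if len(chosen) == count:
                return chosen
    raise ReferenceError(
        f"cannot place {count} regions with separation {min_separation}; bundle too small"
    )


def plant_case(
    bundle: ReferenceBundle,
    module_kind: str,
    k_loci: int,
    n_decoy_loci: int,
    params: SimulationParams,
    n_seeds: int = 1,
    rng_seed: Optional[int] = None,
    min_gene_separation: int = 5,
) -> tuple[list[Marker], list[str], PlantedTruth]:
    """Bury a true module in the bundle and emit benchmark loci for it.

    Picks ``k_loci`` well-separated target genes plus ``n_decoy_loci``
    decoy genes, plants the module (pathway membership, a fresh domain
    family, or an interaction clique) on the targets and on ``n_seeds``
    far-away genes designated as the known disease genes, then registers one
    SNP inside every target and decoy gene. The SNPs (truth first), the seed
    list and the full truth table are returned; the bundle is modified in
    place. Separation is in gene-index units per chromosome, sized so that
    default bystander windows of neighbouring loci never share genes.
    """
    if module_kind not in ("pathway", "domain", "ppi"):
        raise ReferenceError(f"unknown module kind {module_kind!r}")
    if not (1 <= n_seeds <= 3):
        raise ReferenceError("n_seeds must be between 1 and 3")
    rng = np.random.default_rng(
        params.rng_seed + 600_011 if rng_seed is None else rng_seed
    )
    genes = sorted(bundle.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))
    order = [int(i) for i in rng.permutation(len(genes))]

    target_idx = _pick_separated(order, genes, k_loci + n_decoy_loci, min_gene_separation)
    truth_idx, decoy_idx = target_idx[:k_loci], target_idx[k_loci:]
    seed_idx = _pick_separated(order, genes, n_seeds, min_gene_separation, taken=target_idx)

    truth_genes = [genes[i].gene_id for i in truth_idx]
    seed_genes = [genes[i].gene_id for i in seed_idx]
    module_members = truth_genes + seed_genes

    if module_kind == "pathway":
        planted_id = PLANTED_SET_ID
        bundle.add_gene_set(
            GeneSet(planted_id, "planted module", PLANTED_SOURCE, frozenset(module_members))
        )
    elif module_kind == "domain":
        planted_id = PLANTED_FAMILY_ID
        L = params.protein_len_per_domain
        consensus = rng.integers(0, AMINO_ACIDS.size, L)
        for gid in module_members:
            pids = bundle.gene_proteins.get(gid)
            if not pids:
                raise ReferenceError(f"gene {gid} has no protein; run with make_proteins=True")
            pid = pids[0]
            offset = len(bundle.proteins[pid].residues)
            extra = "".join(AMINO_ACIDS[_mutated_consensus(consensus, params.domain_noise, rng)])
            bundle.extend_protein(pid, extra)
            bundle.add_domain_hit(DomainHit(pid, planted_id, offset, offset + L, 100.0))
    else:  # ppi clique
        planted_id = "PLANTED_CLIQUE"
        for i, a in enumerate(module_members):
            for b in module_members[i + 1 :]:
                bundle.add_edge(a, b, PLANTED_SOURCE)

    snps: list[Marker] = []
    for t, i in enumerate(truth_idx, start=1):
        g = genes[i]
        pos = int(rng.integers(g.start, g.end))
        snps.append(Marker(f"rs_t{t:02d}", "snp", g.chrom, pos))
    for d, i in enumerate(decoy_idx, start=1):
        g = genes[i]
        pos = int(rng.integers(g.start, g.end))
        snps.append(Marker(f"rs_d{d:02d}", "snp", g.chrom, pos))
    for m in snps:
        bundle.add_marker(m)

    truth = PlantedTruth(
        module_kind=module_kind,
        planted_id=planted_id,
        disease_gene_ids=tuple(truth_genes),
        seed_gene_ids=tuple(seed_genes),
        snp_markers=tuple(m.marker_id for m in snps),
        decoy_summary=f"{n_decoy_loci} decoy loci at {[genes[i].gene_id for i in decoy_idx]}",
    )
    return snps, seed_genes, truth


def write_case(
    directory: Union[str, Path],
    bundle: ReferenceBundle,
    snps: Sequence[Marker],
    seeds: Sequence[str],
    truth: PlantedTruth,
    params: SimulationParams,
) -> None:
    """Write a complete planted case directory: reference files plus
    snps.txt, seeds.txt, truth.tsv and the generator configuration."""
    directory = Path(directory)
    write_bundle(bundle, directory)
    _write_params(params, directory / "params.txt")
    with open(directory / "snps.txt", "w") as fh:
        for m in snps:
            fh.write(m.marker_id + "\n")
    with open(directory / "seeds.txt", "w") as fh:
        for s in seeds:
            fh.write(s + "\n")
    with open(directory / "truth.tsv", "w") as fh:
        fh.write("field\tvalue\n")
        fh.write(f"module_kind\t{truth.module_kind}\n")
        fh.write(f"planted_id\t{truth.planted_id}\n")
        fh.write(f"disease_genes\t{','.join(truth.disease_gene_ids)}\n")
        fh.write(f"seed_genes\t{','.join(truth.seed_gene_ids)}\n")
        fh.write(f"snp_markers\t{','.join(truth.snp_markers)}\n")
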