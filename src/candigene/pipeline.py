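"""Run orchestration and tabular prediction reports.

:func:`run_pipeline` builds the gene search space from the configured loci,
runs each selected method, merges the per-method predictions into a single
ranked report and writes ``predictions.tsv``, ``associations.tsv``,
``search_space.bed`` and ``run.log`` into the output directory. Outputs are
deterministic: identical configuration and inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from . import cmp as cmp_engine
from . import cps as cps_engine
from .alignment import ScoringScheme, default_scheme
from .bundle import ReferenceBundle
from .io import discover_reference, load_reference
from .loci import (
    DEFAULT_WINDOW_BP,
    SearchSpace,
    build_search_space,
    parse_interval_lines,
    parse_snp_lines,
    space_to_bed,
)
from .models import STAT_COUNT, STAT_P, CandidatePrediction

PathLike = Union[str, Path]

SEEDED_METHODS = ("CPS-s", "PPI-s", "CMP-s")
AB_INITIO_METHODS = ("CPS-ab", "PPI-ab", "CMP-ab")
ALL_METHODS = ("CPS-s", "CPS-ab", "PPI-s", "PPI-ab", "CMP-s", "CMP-ab")

INPUT_MODES = ("snps_adjacent", "snps_bystander", "intervals")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Everything one prediction run needs.

    ``reference`` maps roles (genes, gene_sets, edges, domains, proteins,
    markers, phenotypes) to file paths; ``snps``/``intervals`` point at batch
    locus input files; seeds come either from a phenotype record
    (``seed_phenotype``) or an explicit list (``seeds``).
    """

    reference: dict[str, PathLike]
    out_dir: PathLike
    input_mode: str = "snps_bystander"
    snps: Optional[PathLike] = None
    intervals: Optional[PathLike] = None
    window_bp: int = DEFAULT_WINDOW_BP
    seeds: tuple[str, ...] = ()
    seed_phenotype: Optional[str] = None
    methods: tuple[str, ...] = ("CPS-s", "CPS-ab")
    alpha: float = 0.05
    chi2_threshold: float = 3.84
    s_min: float = 0.0
    min_loci: int = 2
    sources: Optional[tuple[str, ...]] = None
    bonferroni: bool = False
    combinations: str = "singles"
    max_family_universe_freq: Optional[float] = None
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix: str = "BLOSUM62"
    rng_seed: int = 0  # used by the simulate subcommand only

    def validate(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ConfigError(f"input_mode must be one of {INPUT_MODES}")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ConfigError(f"unknown methods {bad}")
        if not self.methods:
            raise ConfigError("no methods selected")
        needs_seeds = [m for m in self.methods if m in SEEDED_METHODS]
        if needs_seeds and not (self.seeds or self.seed_phenotype):
            raise ConfigError(f"methods {needs_seeds} require seeds")
        if self.input_mode.startswith("snps") and not self.snps:
            raise ConfigError("SNP input modes require an snps file")
        if self.input_mode == "intervals" and not self.intervals:
            raise ConfigError("intervals mode requires an intervals file")
        if "genes" not in self.reference:
            raise ConfigError("reference must include a genes file")


@dataclass(frozen=True)
class ReportRow:
    """One rendered prediction row of the final report."""

    locus_label: str
    gene: str
    method: str
    common_property: str
    seed_genes: str  # comma-joined or "-"
    score: str  # "P=...", "S=..." or "-"
    relative_rank: int


def render_score(pred: CandidatePrediction) -> str:
    if pred.statistic_kind == STAT_P:
        return f"P={pred.statistic:.2g}"
    if pred.statistic_kind == STAT_COUNT:
        return "-"  # interaction evidence renders no score
    return f"S={pred.statistic:.2f}"


def merge_reports(per_method: Sequence[Sequence[CandidatePrediction]]) -> list[ReportRow]:
    """Union of all methods' rows, one row per (gene, locus, method, evidence).

    A gene predicted by several methods keeps one row per method. Rows are
    sorted by locus label, method and rank; input order never matters.
    """
    rows = []
    for preds in per_method:
        for p in preds:
            for lid in p.locus_ids:
                rows.append(
                    ReportRow(
                        locus_label=lid,
                        gene=p.symbol,
                        method=p.method,
                        common_property=p.evidence_name,
                        seed_genes=",".join(p.seed_genes) if p.seed_genes else "-",
                        score=render_score(p),
                        relative_rank=p.relative_rank or 0,
                    )
                )
    rows.sort(key=lambda r: (r.locus_label, r.method, r.relative_rank, r.gene, r.common_property))
    return rows


PREDICTIONS_HEADER = (
    "locus_label\tpredicted_gene\tmethod\tcommon_property\tseed_genes\tscore\trelative_rank"
)


def render_predictions(rows: Sequence[ReportRow]) -> str:
    lines = [PREDICTIONS_HEADER]
    for r in rows:
        lines.append(
            f"{r.locus_label}\t{r.gene}\t{r.method}\t{r.common_property}\t"
            f"{r.seed_genes}\t{r.score}\t{r.relative_rank}"
        )
    return "\n".join(lines) + "\n"


def parse_predictions(path: PathLike) -> list[ReportRow]:
    """Reload a predictions.tsv into ReportRow records (round-trip safe)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != PREDICTIONS_HEADER:
            raise ConfigError(f"{path}: unexpected header {header!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != 7:
                raise ConfigError(f"{path}: bad row {line!r}")
            rows.append(ReportRow(f[0], f[1], f[2], f[3], f[4], f[5], int(f[6])))
    return rows


ASSOCIATIONS_HEADER = (
    "method\tkind\tid\tsource\tname\tstatistic\tstatistic_value\t"
    "observed\tK\tn\tN\tloci_hit\tretained"
)


def render_associations(
    pathway_assocs: Sequence[tuple[str, cps_engine.PathwayAssociation]],
    enrichments: Sequence[tuple[str, cmp_engine.DomainEnrichment]],
) -> str:
    """Full-precision statistics table for pathways and domain families,
    tagged with the method that evaluated each record."""
    lines = [ASSOCIATIONS_HEADER]
    for method, a in pathway_assocs:
        c = a.counts
        lines.append(
            f"{method}\tpathway\t{a.set_id}\t{a.source_db}\t{a.name}\tp\t{a.p_value:.10g}\t"
            f"{c.k}\t{c.K}\t{c.n}\t{c.N}\t{a.loci_hit}\t{int(a.retained)}"
        )
    for method, e in enrichments:
        lines.append(
            f"{method}\tdomain\t{e.family_id}\t-\t{e.family_id}\tchi2_min\t{e.chi2_min:.10g}\t"
            f"{e.o_gene}\t-\t-\t-\t{e.o_locus}\t{int(e.retained)}"
        )
    return "\n".join(lines) + "\n"


def _resolve_seeds(config: RunConfig, bundle: ReferenceBundle) -> set[str]:
    seeds: set[str] = set()
    if config.seed_phenotype:
        ph = bundle.phenotypes.get(config.seed_phenotype)
        if ph is None:
            raise ConfigError(f"unknown phenotype {config.seed_phenotype!r}")
        seeds |= set(ph.seed_genes)
    for tok in config.seeds:
        gid = bundle.resolve_gene(tok)
        if gid is None:
            raise ConfigError(f"unknown seed gene {tok!r}")
        seeds.add(gid)
    return seeds


def build_space_from_config(config: RunConfig, bundle: ReferenceBundle) -> SearchSpace:
    if config.input_mode == "intervals":
        with open(config.intervals) as fh:
            specs = parse_interval_lines(fh, bundle)
        return build_search_space(specs, "intervals", bundle)
    with open(config.snps) as fh:
        markers = parse_snp_lines(fh, bundle)
    mode = "adjacent" if config.input_mode == "snps_adjacent" else "bystander"
    return build_search_space(markers, mode, bundle, window_bp=config.window_bp)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a full prediction run; returns the paths written.

    Any configuration violation or method failure raises (no partial silent
    output); a run with zero predictions is still a success and is reported
    in the log.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = ["# effective configuration"]
    for f in dataclasses.fields(config):
        log_lines.append(f"{f.name} = {getattr(config, f.name)}")

    bundle = load_reference(config.reference)
    for w in bundle.load_warnings:
        log_lines.append(f"warning: {w}")
    space = build_space_from_config(config, bundle)
    log_lines.append(f"loci = {len(space.loci)}")
    log_lines.append(f"space_genes = {space.universe_n}")

    ab_methods = [m for m in config.methods if m in AB_INITIO_METHODS]
    if ab_methods and len(space.loci) < 2:
        raise ConfigError(f"methods {ab_methods} require >= 2 loci, got {len(space.loci)}")

    seeds = _resolve_seeds(config, bundle) if any(
        m in SEEDED_METHODS for m in config.methods
    ) else set()
    if seeds:
        log_lines.append(f"seed_genes = {','.join(sorted(seeds))}")

    scheme: Optional[ScoringScheme] = None
    if any(m.startswith("CMP") for m in config.methods):
        if config.matrix == "BLOSUM62" and config.gap_open == 11 and config.gap_extend == 1:
            scheme = default_scheme()
        else:
            scheme = ScoringScheme.from_preset(
                config.matrix, config.gap_open, config.gap_extend
            )

    per_method: list[list[CandidatePrediction]] = []
    pathway_assocs: list[tuple[str, cps_engine.PathwayAssociation]] = []
    enrichments: list[tuple[str, cmp_engine.DomainEnrichment]] = []
    for method in config.methods:
        if method == "CPS-s":
            assocs, preds = cps_engine.cps_seeded(
                space, seeds, bundle, alpha=config.alpha, sources=config.sources,
                bonferroni=config.bonferroni,
            )
            pathway_assocs.extend(("CPS-s", a) for a in assocs)
        elif method == "CPS-ab":
            assocs, preds = cps_engine.cps_ab_initio(
                space, bundle, alpha=config.alpha, min_loci=config.min_loci,
                sources=config.sources, bonferroni=config.bonferroni,
            )
            pathway_assocs.extend(("CPS-ab", a) for a in assocs)
        elif method == "PPI-s":
            preds = cps_engine.ppi_seeded(space, seeds, bundle)
        elif method == "PPI-ab":
            preds = cps_engine.ppi_ab_initio(space, bundle)
        elif method == "CMP-s":
            preds = cmp_engine.cmp_seeded(space, seeds, bundle, scheme, s_min=config.s_min)
        else:  # CMP-ab
            enr, preds = cmp_engine.cmp_ab_initio(
                space, bundle, chi2_threshold=config.chi2_threshold,
                min_loci=config.min_loci, combinations_mode=config.combinations,
                max_family_universe_freq=config.max_family_universe_freq,
            )
            enrichments.extend(("CMP-ab", e) for e in enr)
        log_lines.append(f"{method}: {len(preds)} predictions")
        per_method.append(preds)

    rows = merge_reports(per_method)
    log_lines.append(f"total_report_rows = {len(rows)}")
    if not rows:
        log_lines.append("no predictions made")

    paths = {
        "predictions": out_dir / "predictions.tsv",
        "associations": out_dir / "associations.tsv",
        "search_space": out_dir / "search_space.bed",
        "log": out_dir / "run.log",
    }
    paths["predictions"].write_text(render_predictions(rows))
    paths["associations"].write_text(render_associations(pathway_assocs, enrichments))
    paths["search_space"].write_text(space_to_bed(space))
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths


# ------------------------------------------------------------- flat config

def parse_config_file(path: PathLike) -> dict[str, str]:
    """Flat ``key = value`` configuration; '#' comments and blanks skipped."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            if not sep:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            out[key.strip()] = value.strip()
    return out


def config_from_mapping(mapping: dict[str, str]) -> RunConfig:
    """Build a RunConfig from flat string keys (file or CLI overrides).

    Reference roles are given as ``genes=...``, ``gene_sets=...`` etc., or a
    whole directory of standard names as ``reference_dir=...``.
    """
    reference: dict[str, PathLike] = {}
    if "reference_dir" in mapping:
        reference.update(discover_reference(mapping.pop("reference_dir")))
    for role in ("genes", "gene_sets", "edges", "domains", "proteins", "markers", "phenotypes"):
        if role in mapping:
            reference[role] = mapping.pop(role)
    kwargs: dict = {"reference": reference}
    converters = {
        "window_bp": int, "alpha": float, "chi2_threshold": float, "s_min": float,
        "min_loci": int, "bonferroni": lambda v: v.lower() in ("1", "true", "yes"),
        "max_family_universe_freq": float, "gap_open": float, "gap_extend": float,
        "rng_seed": int,
        "methods": lambda v: tuple(t.strip() for t in v.split(",") if t.strip()),
        "seeds": lambda v: tuple(t.strip() for t in v.split(",") if t.strip()),
        "sources": lambda v: tuple(t.strip() for t in v.split(",") if t.strip()),
    }
    for key, value in mapping.items():
        if not hasattr(RunConfig, "__dataclass_fields__") or key not in RunConfig.__dataclass_fields__:
            raise ConfigError(f"unknown configuration key {key!r}")
        kwargs[key] = converters.get(key, str)(value)
    if "out_dir" not in kwargs:
        raise ConfigError("out_dir is required")
    return RunConfig(**kwargs)
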