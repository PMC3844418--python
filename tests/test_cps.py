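"""Pathway scanning: Fisher statistic, seeded/ab-initio modes, PPI, ranking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from _oracles import fisher_tail_fraction
from candigene.cps import (
    ContingencyCounts,
    cps_ab_initio,
    cps_seeded,
    fisher_exact_greater,
    ppi_ab_initio,
    ppi_seeded,
    rank_predictions,
)
from candigene.loci import build_search_space
from candigene.models import CandidatePrediction, Marker


def _snp(pos, mid, chrom="chr1"):
    return Marker(mid, "snp", chrom, pos)


class TestFisher:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((0, 5, 3, 20), 1.0),
            ((1, 1, 1, 2), 0.5),
            ((2, 2, 2, 4), 1 / 6),
        ],
    )
    def test_hand_values(self, counts, expected):
        assert fisher_exact_greater(ContingencyCounts(*counts)) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [(3, 2, 5, 10), (1, 5, 6, 5), (2, 6, 1, 5)])
    def test_invalid_counts_raise(self, bad):
        with pytest.raises(ValueError):
            ContingencyCounts(*bad)

    def test_matches_exact_rational_oracle(self):
        for N in range(1, 13):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(n, K) + 1):
                        got = fisher_exact_greater(ContingencyCounts(k, n, K, N))
                        want = float(fisher_tail_fraction(k, n, K, N))
                        assert got == pytest.approx(want, abs=1e-13)

    def test_matches_scipy_survival_function(self):
        # independent library cross-check on larger margins
        for (k, n, K, N) in [(4, 20, 5, 200), (2, 30, 8, 3000), (10, 48, 15, 200)]:
            got = fisher_exact_greater(ContingencyCounts(k, n, K, N))
            want = float(hypergeom.sf(k - 1, N, K, n))
            assert got == pytest.approx(want, rel=1e-9)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(2, 40), st.data())
    def test_strictly_decreasing_in_k(self, N, data):
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        lo, hi = max(0, n + K - N), min(n, K)
        ps = [
            fisher_exact_greater(ContingencyCounts(k, n, K, N))
            for k in range(max(lo, 0), hi + 1)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))


@pytest.fixture
def planted_space(tiny_bundle):
    """Three bystander loci over G03, G05, G09; PW1 also holds seed G01."""
    snps = [_snp(23_000, "s1"), _snp(43_000, "s2"), _snp(83_000, "s3")]
    return build_search_space(snps, "bystander", tiny_bundle, window_bp=8_000)


class TestCpsSeeded:
    def test_counts_and_pvalue_recomputed_directly(self, tiny_bundle, planted_space):
        assocs, preds = cps_seeded(planted_space, {"G01"}, tiny_bundle, alpha=1.0)
        pw1 = next(a for a in assocs if a.set_id == "PW1")
        # space = {G03, G05, G09}; PW1 = {G01,G03,G05,G09}; universe = 10
        assert (pw1.counts.k, pw1.counts.n, pw1.counts.K, pw1.counts.N) == (3, 3, 4, 10)
        assert pw1.p_value == pytest.approx(float(hypergeom.sf(2, 10, 4, 3)), rel=1e-12)
        assert pw1.loci_hit == 3
        assert {p.gene_id for p in preds} >= {"G03", "G05", "G09"}

    def test_seed_never_a_candidate(self, tiny_bundle):
        # locus window covering seed G01 itself
        space = build_search_space(
            [_snp(3_000, "s0"), _snp(23_000, "s1")], "bystander", tiny_bundle, window_bp=8_000
        )
        _, preds = cps_seeded(space, {"G01"}, tiny_bundle, alpha=1.0)
        assert all(p.gene_id != "G01" for p in preds)
        # but the seed inside a locus still counts toward the overlap k
        assocs, _ = cps_seeded(space, {"G01"}, tiny_bundle, alpha=1.0)
        pw1 = next(a for a in assocs if a.set_id == "PW1")
        assert "G01" in pw1.overlap_genes

    def test_no_shared_pathway_yields_nothing(self, tiny_bundle, planted_space):
        # G07 belongs to no gene set
        assocs, preds = cps_seeded(planted_space, {"G07"}, tiny_bundle, alpha=1.0)
        assert assocs == [] and preds == []

    def test_alpha_one_reports_all_overlap_genes(self, tiny_bundle, planted_space):
        _, preds = cps_seeded(planted_space, {"G01"}, tiny_bundle, alpha=1.0)
        assert {p.gene_id for p in preds} == {"G03", "G05", "G09"}

    def test_requires_seeds(self, tiny_bundle, planted_space):
        with pytest.raises(ValueError):
            cps_seeded(planted_space, set(), tiny_bundle)


class TestCpsAbInitio:
    def test_single_locus_pathway_filtered_by_min_loci(self, tiny_bundle):
        # one window containing both G02 and G04 (all of PW2) + another locus
        space = build_search_space(
            [_snp(21_000, "wide"), _snp(83_000, "far")],
            "bystander", tiny_bundle, window_bp=40_000,
        )
        assocs, _ = cps_ab_initio(space, tiny_bundle, alpha=1.0, min_loci=2)
        assert all(a.loci_hit >= 2 for a in assocs)
        assert "PW2" not in {a.set_id for a in assocs}

    def test_seeded_and_ab_initio_agree_on_pvalue(self, tiny_bundle, planted_space):
        s_assocs, _ = cps_seeded(planted_space, {"G01"}, tiny_bundle, alpha=1.0)
        ab_assocs, _ = cps_ab_initio(planted_space, tiny_bundle, alpha=1.0)
        p_seeded = next(a.p_value for a in s_assocs if a.set_id == "PW1")
        p_ab = next(a.p_value for a in ab_assocs if a.set_id == "PW1")
        assert p_seeded == p_ab

    def test_filters_disabled_reports_every_annotated_space_gene(self, tiny_bundle):
        space = build_search_space(
            [_snp(21_000, "wide"), _snp(83_000, "far")],
            "bystander", tiny_bundle, window_bp=40_000,
        )
        _, preds = cps_ab_initio(space, tiny_bundle, alpha=1.0, min_loci=1)
        annotated = set()
        for gs in tiny_bundle.sets_by_source():
            annotated |= gs.members & space.genes
        assert {p.gene_id for p in preds} == annotated

    def test_requires_two_loci(self, tiny_bundle):
        space = build_search_space([_snp(23_000, "s1")], "bystander", tiny_bundle)
        with pytest.raises(ValueError):
            cps_ab_initio(space, tiny_bundle)


class TestPpi:
    def test_seeded_counts_distinct_seed_partners(self, tiny_bundle):
        # G02 interacts with seed G01; G04 with seed G03
        space = build_search_space(
            [_snp(13_000, "sA"), _snp(33_000, "sB")], "bystander", tiny_bundle, window_bp=8_000
        )
        preds = ppi_seeded(space, {"G01", "G03"}, tiny_bundle)
        by_gene = {p.gene_id: p for p in preds}
        assert by_gene["G02"].statistic == 1 and by_gene["G02"].seed_genes == ("G01",)
        assert by_gene["G04"].statistic == 1 and by_gene["G04"].seed_genes == ("G03",)

    def test_seed_inside_locus_not_emitted(self, tiny_bundle):
        space = build_search_space(
            [_snp(3_000, "s0"), _snp(43_000, "s2")], "bystander", tiny_bundle, window_bp=8_000
        )
        preds = ppi_seeded(space, {"G05"}, tiny_bundle)  # G05 interacts with G01
        assert all(p.gene_id != "G05" for p in preds)
        assert {p.gene_id for p in preds} == {"G01"}

    def test_ab_initio_cross_locus_only(self, tiny_bundle):
        # G01-G02 inside one wide locus: ignored; G01-G05 across loci: kept
        space = build_search_space(
            [_snp(11_000, "wide"), _snp(43_000, "far")],
            "bystander", tiny_bundle, window_bp=25_000,
        )
        preds = ppi_ab_initio(space, tiny_bundle)
        by_gene = {p.gene_id: p.statistic for p in preds}
        # G02 interacts only with G01 inside the same single locus: excluded
        assert "G02" not in by_gene
        assert by_gene == {"G01": 1.0, "G05": 1.0, "G03": 1.0, "G04": 1.0}


class TestRanking:
    def _pred(self, gene, stat, kind="p", locus="L1", method="CPS-s"):
        return CandidatePrediction(gene, gene, (locus,), method, "E", "E", stat, kind)

    def test_orders_by_p_then_symbol(self):
        preds = rank_predictions(
            [self._pred("B", 0.31), self._pred("A", 0.01), self._pred("C", 0.08)]
        )
        assert [(p.gene_id, p.relative_rank) for p in preds] == [
            ("A", 1), ("C", 2), ("B", 3)
        ]

    def test_ties_break_on_symbol_with_distinct_ranks(self):
        preds = rank_predictions([self._pred("B", 0.05), self._pred("A", 0.05)])
        assert [(p.gene_id, p.relative_rank) for p in preds] == [("A", 1), ("B", 2)]

    def test_interaction_rows_rank_after_pathway_rows(self):
        preds = rank_predictions(
            [
                self._pred("Z", 5, kind="count", method="PPI-s"),
                self._pred("M", 0.9),
            ]
        )
        assert [p.gene_id for p in preds] == ["M", "Z"]
        assert [p.relative_rank for p in preds] == [1, 2]

    def test_permutation_invariant(self):
        rows = [self._pred(g, s) for g, s in [("A", 0.2), ("B", 0.1), ("C", 0.3)]]
        fwd = rank_predictions(list(rows))
        rev = rank_predictions(rows[::-1])
        assert [(p.gene_id, p.relative_rank) for p in fwd] == [
            (p.gene_id, p.relative_rank) for p in rev
        ]
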