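"""Domain profiling: similarity scores and chi-square enrichment."""

import pytest

from candigene.bundle import ReferenceBundle
from candigene.cmp import (
    chi2_component,
    cmp_ab_initio,
    cmp_seeded,
    domain_similarity,
)
from candigene.loci import IntervalSpec, build_search_space
from candigene.models import DomainHit, Gene, Marker, ProteinRecord


def _bundle_with_domains(assignments, seqs):
    """assignments: {gene_id: [(family, subseq), ...]} laid out 10kb apart."""
    genes, proteins, hits = [], [], []
    for i, gid in enumerate(sorted(assignments)):
        start = 1000 + i * 10_000
        genes.append(Gene(gid, gid, "chr1", start, start + 5000, "+"))
        residues = "".join(seq for _, seq in assignments[gid])
        pid = f"{gid}_P1"
        proteins.append(ProteinRecord(pid, gid, residues))
        off = 0
        for fam, seq in assignments[gid]:
            hits.append(DomainHit(pid, fam, off, off + len(seq), 50.0))
            off += len(seq)
    _ = seqs
    return ReferenceBundle(genes=genes, proteins=proteins, domain_hits=hits)


class TestDomainSimilarity:
    def test_identical_instances_normalize_to_one(self):
        seq = "MKTAYIAKQRQISFVK"
        bundle = _bundle_with_domains({"GA": [("F1", seq)], "GB": [("F1", seq)]}, None)
        ha = bundle.hits_by_protein["GA_P1"][0]
        hb = bundle.hits_by_protein["GB_P1"][0]
        sim = domain_similarity(ha, hb, bundle)
        assert sim.s_norm == 1.0
        assert sim.raw_score == sim.self_a == sim.self_b

    def test_substituted_instance_in_unit_interval_and_matches_recomputation(self):
        a, b = "MKTAYIAKQRQISFVK", "MKTAYIARQRQISFVK"  # one K->R substitution
        bundle = _bundle_with_domains({"GA": [("F1", a)], "GB": [("F1", b)]}, None)
        sim = domain_similarity(
            bundle.hits_by_protein["GA_P1"][0], bundle.hits_by_protein["GB_P1"][0], bundle
        )
        from candigene.alignment import default_scheme, smith_waterman

        raw = smith_waterman(a, b, default_scheme())
        want = raw / max(
            smith_waterman(a, a, default_scheme()), smith_waterman(b, b, default_scheme())
        )
        assert 0.0 < sim.s_norm < 1.0
        assert sim.s_norm == pytest.approx(want)

    def test_family_mismatch_rejected(self):
        bundle = _bundle_with_domains(
            {"GA": [("F1", "MKTAYI")], "GB": [("F2", "MKTAYI")]}, None
        )
        with pytest.raises(ValueError, match="families"):
            domain_similarity(
                bundle.hits_by_protein["GA_P1"][0],
                bundle.hits_by_protein["GB_P1"][0],
                bundle,
            )


class TestCmpSeeded:
    def _space(self, bundle, gene_ids):
        specs = [
            IntervalSpec.explicit(
                bundle.genes[g].chrom, bundle.genes[g].start, bundle.genes[g].end,
                locus_id=f"L_{g}",
            )
            for g in gene_ids
        ]
        return build_search_space(specs, "intervals", bundle)

    def test_identity_scores_one_and_no_shared_family_is_silent(self):
        seq = "MKTAYIAKQRQISFVK"
        bundle = _bundle_with_domains(
            {"CAND": [("F1", seq)], "OTHER": [("F9", "WWNPGRRQCC")], "SEED": [("F1", seq)]},
            None,
        )
        space = self._space(bundle, ["CAND", "OTHER"])
        preds = cmp_seeded(space, {"SEED"}, bundle)
        assert [p.gene_id for p in preds] == ["CAND"]
        assert preds[0].statistic == 1.0
        assert preds[0].seed_genes == ("SEED",)
        assert preds[0].method == "CMP-s"

    def test_max_rule_picks_best_family_and_is_order_invariant(self):
        near = "MKTAYIAKQRQISFVK"
        nearish = "MKTAYIARQRQISFVK"
        far = "MKTWWWWKQRQISPPP"
        bundle = _bundle_with_domains(
            {
                "CAND": [("F1", near), ("F2", far)],
                "SEED1": [("F2", "MKTAYIAKQRQISFVK")],
                "SEED2": [("F1", nearish)],
            },
            None,
        )
        space = self._space(bundle, ["CAND"])
        preds = cmp_seeded(space, {"SEED1", "SEED2"}, bundle)
        preds_rev = cmp_seeded(space, {"SEED2", "SEED1"}, bundle)
        assert len(preds) == 1
        best = preds[0]
        assert best.evidence == "F1" and best.seed_genes == ("SEED2",)
        assert (best.evidence, best.statistic) == (preds_rev[0].evidence, preds_rev[0].statistic)

    def test_s_min_threshold_gates(self):
        bundle = _bundle_with_domains(
            {"CAND": [("F1", "MKTWWWWKQRQISPPP")], "SEED": [("F1", "MKTAYIAKQRQISFVK")]},
            None,
        )
        space = self._space(bundle, ["CAND"])
        all_preds = cmp_seeded(space, {"SEED"}, bundle, s_min=0.0)
        assert len(all_preds) == 1
        gated = cmp_seeded(space, {"SEED"}, bundle, s_min=all_preds[0].statistic + 0.01)
        assert gated == []


class TestChi2:
    @pytest.mark.parametrize("o,e,want", [(1.0, 1.0, 0.0), (5, 1, 16.0), (2, 1, 1.0)])
    def test_component_arithmetic(self, o, e, want):
        assert chi2_component(o, e) == want

    def test_nonpositive_expectation_rejected(self):
        with pytest.raises(ValueError):
            chi2_component(3, 0)


def _enrichment_fixture(n_universe=200, bearing=5, per_locus=True):
    """N genes; planted family on `bearing` genes either spread over that many
    loci or packed into one; loci are one explicit interval per region."""
    genes = [
        Gene(f"G{i:03d}", f"G{i:03d}", "chr1", 1000 + i * 10_000, 6000 + i * 10_000, "+")
        for i in range(n_universe)
    ]
    proteins, hits = [], []
    seq = "MKTAYIAKQRQISFVKSHFS"
    if per_locus:
        carrier_idx = [10 + 20 * j for j in range(bearing)]  # well separated
    else:
        carrier_idx = list(range(10, 10 + bearing))  # one paralog run
    for i in carrier_idx:
        pid = f"G{i:03d}_P1"
        proteins.append(ProteinRecord(pid, f"G{i:03d}", seq))
        hits.append(DomainHit(pid, "FP", 0, len(seq), 60.0))
    bundle = ReferenceBundle(genes=genes, proteins=proteins, domain_hits=hits)
    if per_locus:
        specs = [
            IntervalSpec.explicit("chr1", genes[i].start, genes[i].end, locus_id=f"L{j}")
            for j, i in enumerate(carrier_idx)
        ]
        # pad the space with decoy loci holding non-carriers (n = bearing + 35)
        specs += [
            IntervalSpec.explicit("chr1", genes[i].start, genes[i].end, locus_id=f"D{j}")
            for j, i in enumerate(range(150, 185))
        ]
    else:
        lo = genes[carrier_idx[0]].start
        hi = genes[carrier_idx[-1]].end
        specs = [IntervalSpec.explicit("chr1", lo, hi, locus_id="CL")]
        specs += [
            IntervalSpec.explicit("chr1", genes[i].start, genes[i].end, locus_id=f"D{j}")
            for j, i in enumerate(range(150, 185))
        ]
    space = build_search_space(specs, "intervals", bundle)
    return bundle, space


class TestCmpAbInitio:
    def test_planted_family_spread_over_loci(self):
        bundle, space = _enrichment_fixture(bearing=5, per_locus=True)
        # n = 40 space genes, K = 5, N = 200 -> e = 1.0; o_gene = o_locus = 5
        enr, preds = cmp_ab_initio(space, bundle)
        fam = next(e for e in enr if e.family_id == "FP")
        assert fam.e == pytest.approx(1.0)
        assert fam.o_gene == fam.o_locus == 5
        assert fam.chi2_gene == fam.chi2_locus == fam.chi2_min == pytest.approx(16.0)
        assert fam.retained and fam.direction == "over"
        assert {p.gene_id for p in preds} == set(fam.bearing_genes)
        assert all(p.statistic == pytest.approx(16.0) for p in preds)

    def test_paralog_cluster_collapses_to_zero(self):
        bundle, space = _enrichment_fixture(bearing=5, per_locus=False)
        # all five carriers inside ONE locus: o_locus = 1 <= e -> no evidence
        enr, preds = cmp_ab_initio(space, bundle)
        fam = next(e for e in enr if e.family_id == "FP")
        assert fam.o_locus == 1
        assert fam.chi2_locus == 0.0 and fam.chi2_min == 0.0
        assert not fam.retained and preds == []

    def test_direction_under_never_predicted(self):
        # family on many universe genes but few space genes
        genes = [
            Gene(f"G{i:03d}", f"G{i:03d}", "chr1", 1000 + i * 10_000, 6000 + i * 10_000, "+")
            for i in range(100)
        ]
        seq = "MKTAYIAKQRQISFVKSHFS"
        proteins = [ProteinRecord(f"G{i:03d}_P1", f"G{i:03d}", seq) for i in range(60)]
        hits = [DomainHit(f"G{i:03d}_P1", "FC", 0, len(seq), 10.0) for i in range(60)]
        bundle = ReferenceBundle(genes=genes, proteins=proteins, domain_hits=hits)
        specs = [
            IntervalSpec.explicit("chr1", genes[i].start, genes[i].end, locus_id=f"L{i}")
            for i in (0, 70, 80, 90)  # one carrier, three non-carriers
        ]
        space = build_search_space(specs, "intervals", bundle)
        enr, preds = cmp_ab_initio(space, bundle, chi2_threshold=0.0, min_loci=1)
        fam = next(e for e in enr if e.family_id == "FC")
        assert fam.o_gene < fam.e and fam.direction == "under"
        assert not fam.retained and preds == []

    def test_pairs_mode_and_promiscuity_filter(self):
        genes = [
            Gene(f"G{i:02d}", f"G{i:02d}", "chr1", 1000 + i * 10_000, 6000 + i * 10_000, "+")
            for i in range(40)
        ]
        seq = "MKTAYIAKQR"
        proteins, hits = [], []
        for i in (0, 10, 20):  # three carriers of the F1+F2 combination
            pid = f"G{i:02d}_P1"
            proteins.append(ProteinRecord(pid, f"G{i:02d}", seq * 2))
            hits.append(DomainHit(pid, "F1", 0, 10, 5.0))
            hits.append(DomainHit(pid, "F2", 10, 20, 5.0))
        bundle = ReferenceBundle(genes=genes, proteins=proteins, domain_hits=hits)
        specs = [
            IntervalSpec.explicit("chr1", genes[i].start, genes[i].end, locus_id=f"L{i}")
            for i in (0, 10, 20, 30)
        ]
        space = build_search_space(specs, "intervals", bundle)
        enr, _ = cmp_ab_initio(space, bundle, combinations_mode="pairs")
        assert "F1+F2" in {e.family_id for e in enr}
        filtered, _ = cmp_ab_initio(
            space, bundle, combinations_mode="pairs", max_family_universe_freq=0.05
        )
        assert filtered == []  # every combo sits on 3/40 = 7.5% of the universe

    def test_requires_two_loci(self, tiny_bundle):
        space = build_search_space(
            [Marker("s1", "snp", "chr1", 23_000)], "bystander", tiny_bundle
        )
        with pytest.raises(ValueError):
            cmp_ab_initio(space, tiny_bundle)
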