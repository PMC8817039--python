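import numpy as np
import pytest

from phenonet.comparative import (
    OverlapSummary,
    ehr_pair_concordance,
    ehr_pairs_from_table,
    harmonize_effect,
    locus_overlap,
    meta_analyze,
)
from phenonet.datatypes import AssociationRecord, Variant
from phenonet.networks import build_phenotype_network, extract_cpa
from phenonet.phewas import run_phewas
from phenonet.simulate import PhenotypeSpec, SimulationConfig, simulate_cohort

from conftest import make_phenotypes


def record(vid, pheno, p, effect=0.1, se=0.02, n=1000):
    return AssociationRecord(
        variant_id=vid,
        phenotype_name=pheno,
        effect=effect,
        standard_error=se,
        p_value=p,
        n_samples=n,
        model="linear",
    )


class TestLocusOverlap:
    def test_identical_cohorts_fully_shared(self):
        stats = [record(f"v{i}", "A", 1e-6) for i in range(5)]
        out = locus_overlap(stats, stats, ["A"])
        assert out[0].n_shared == 5
        assert out[0].ratios == (0.0, 100.0, 0.0)

    def test_disjoint_zero_shared(self):
        s1 = [record(f"v{i}", "A", 1e-6) for i in range(3)]
        s2 = [record(f"w{i}", "A", 1e-6) for i in range(4)]
        out = locus_overlap(s1, s2, ["A"])
        assert out[0].n_shared == 0
        assert out[0].ratios[1] == 0.0

    def test_planted_915_percent(self):
        # 183 shared / 2000 union = 9.15% by construction
        shared = [f"s{i}" for i in range(183)]
        only1 = [f"a{i}" for i in range(1000)]
        only2 = [f"b{i}" for i in range(817)]
        s1 = [record(v, "fatty_liver", 1e-6) for v in shared + only1]
        s2 = [record(v, "fatty_liver", 1e-6) for v in shared + only2]
        out = locus_overlap(s1, s2, ["fatty_liver"])
        assert out[0].ratios[1] == pytest.approx(9.15)

    def test_threshold_applied(self):
        s1 = [record("v0", "A", 1e-6), record("v1", "A", 0.5)]
        s2 = [record("v0", "A", 1e-6), record("v1", "A", 1e-6)]
        out = locus_overlap(s1, s2, ["A"], p_threshold=1e-4)
        assert out[0].n_shared == 1
        assert out[0].n_only_cohort2 == 1

    def test_missing_phenotype_skipped(self):
        s1 = [record("v0", "A", 1e-6)]
        s2 = [record("v0", "B", 1e-6)]
        assert locus_overlap(s1, s2, ["A", "B"]) == []

    def test_ratios_sum_to_100(self, rng):
        for _ in range(20):
            s = OverlapSummary(
                "x",
                int(rng.integers(0, 50)),
                int(rng.integers(1, 50)),
                int(rng.integers(0, 50)),
            )
            assert sum(s.ratios) == pytest.approx(100.0, abs=1e-9)


class TestMetaAnalyze:
    def test_two_identical_cohorts(self):
        s = [record("v0", "A", 1e-3, effect=0.4, se=0.1)]
        out = meta_analyze([s, s])
        assert out[0].meta_effect == pytest.approx(0.4)
        assert out[0].meta_se == pytest.approx(0.1 / np.sqrt(2))

    def test_k_identical_cohorts_se_scaling(self):
        s = [record("v0", "A", 1e-3, effect=0.4, se=0.1)]
        for k in (2, 3, 5):
            out = meta_analyze([s] * k)
            assert out[0].meta_se == pytest.approx(0.1 / np.sqrt(k))

    def test_infinite_se_cohort_ignored_in_limit(self):
        s1 = [record("v0", "A", 1e-3, effect=0.4, se=0.1)]
        s2 = [record("v0", "A", 0.9, effect=-5.0, se=1e6)]
        out = meta_analyze([s1, s2])
        assert out[0].meta_effect == pytest.approx(0.4, abs=1e-6)
        assert out[0].meta_se <= 0.1  # fixed-effect property

    def test_meta_se_leq_min_cohort_se(self, rng):
        s1 = [record("v0", "A", 0.1, effect=0.2, se=float(rng.uniform(0.05, 0.2)))]
        s2 = [record("v0", "A", 0.1, effect=0.3, se=float(rng.uniform(0.05, 0.2)))]
        out = meta_analyze([s1, s2])
        assert out[0].meta_se <= min(s1[0].standard_error, s2[0].standard_error)

    def test_allele_flip_harmonization(self):
        v_ref = Variant("v0", "1", 100, "A", "G")
        v_swapped = Variant("v0", "1", 100, "G", "A")
        assert harmonize_effect(v_ref, v_swapped, 0.4) == -0.4
        v_strand = Variant("v0", "1", 100, "T", "C")  # complement of A/G
        assert harmonize_effect(v_ref, v_strand, 0.4) == 0.4

    def test_strand_ambiguous_dropped(self):
        v1 = Variant("v0", "1", 100, "A", "T")
        v2 = Variant("v0", "1", 100, "A", "T")
        assert harmonize_effect(v1, v2, 0.4) is None
        s = [record("v0", "A", 1e-3)]
        out = meta_analyze([s, s], variant_tables=[{"v0": v1}, {"v0": v2}])
        assert out == []

    def test_power_gain_over_half_cohorts(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            # two half-cohorts measuring one true effect
            beta_true, se = 0.25, 0.08
            b1 = float(rng.normal(beta_true, se))
            b2 = float(rng.normal(beta_true, se))
            from scipy import stats as st

            def rec(b):
                p = max(2 * st.norm.sf(abs(b / se)), np.finfo(float).tiny)
                return [record("v0", "A", p, effect=b, se=se)]

            out = meta_analyze([rec(b1), rec(b2)])
            p1 = rec(b1)[0].p_value
            p2 = rec(b2)[0].p_value
            wins += out[0].meta_p < min(p1, p2)
        assert wins >= 18

    def test_novelty_flag(self):
        strong = [record("v0", "A", 1e-12, effect=0.8, se=0.05)]
        weak = [record("v0", "A", 1e-6, effect=0.4, se=0.08)]
        out = meta_analyze([weak, weak], genomewide_p=1e-8)
        assert out[0].novelty == "significant-in-meta-only"
        out2 = meta_analyze([strong, strong], genomewide_p=1e-8)
        assert out2[0].novelty == "both"

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            meta_analyze([[record("v0", "A", 0.5)]])


class TestEHRPairs:
    def test_continuous_pair_detected(self, rng):
        n = 500
        x = rng.normal(size=n)
        table = make_phenotypes(
            {"a": x, "b": x + 0.3 * rng.normal(size=n), "c": rng.normal(size=n)}
        )
        sig, methods = ehr_pairs_from_table(table)
        assert frozenset(("a", "b")) in sig
        assert methods[frozenset(("a", "b"))] == "pearson"

    def test_binary_pair_chi_squared(self, rng):
        n = 600
        a = (rng.random(n) < 0.5).astype(float)
        b = a.copy()
        flip = rng.choice(n, 60, replace=False)
        b[flip] = 1 - b[flip]
        table = make_phenotypes(
            {"a": a, "b": b}, kinds={"a": "binary", "b": "binary"}
        )
        sig, methods = ehr_pairs_from_table(table)
        assert frozenset(("a", "b")) in sig
        assert methods[frozenset(("a", "b"))] == "chi-squared"

    def test_mixed_pair_point_biserial(self, rng):
        n = 600
        d = (rng.random(n) < 0.4).astype(float)
        y = 1.5 * d + rng.normal(size=n)
        table = make_phenotypes({"d": d, "y": y}, kinds={"d": "binary"})
        sig, methods = ehr_pairs_from_table(table)
        assert methods[frozenset(("d", "y"))] == "point-biserial"
        assert frozenset(("d", "y")) in sig


class TestPairConcordance:
    def test_exact_match_100_percent(self):
        pairs = {frozenset(("a", "b")), frozenset(("b", "c"))}
        per, summary = ehr_pair_concordance(pairs, ehr_pairs=set(pairs))
        assert summary["overall_percent"] == pytest.approx(100.0)

    def test_printed_counts_fixture(self, rng):
        # 1164 PheWAS pairs, 834 shared -> 71.65%
        phenos = [f"P{i:02d}" for i in range(76)]
        import itertools

        all_pairs = [frozenset(p) for p in itertools.combinations(phenos, 2)]
        idx = rng.permutation(len(all_pairs))
        phewas = {all_pairs[i] for i in idx[:1164]}
        shared = {all_pairs[i] for i in idx[:834]}
        extra = {all_pairs[i] for i in idx[1164 : 1164 + (1938 - 834)]}
        ehr = shared | extra
        assert len(ehr) == 1938
        per, summary = ehr_pair_concordance(phewas, ehr_pairs=ehr)
        assert summary["n_shared"] == 834
        assert round(summary["overall_percent"], 2) == 71.65

    def test_zero_pair_phenotype_undefined(self):
        from phenonet.comparative import PairConcordance

        pc = PairConcordance(phenotype="x", n_phewas_pairs=0, n_shared_with_ehr=0)
        assert pc.overlap_percent is None

    def test_overall_is_weighted_mean_of_per_phenotype(self, rng):
        phenos = list("abcdef")
        import itertools

        pool = [frozenset(p) for p in itertools.combinations(phenos, 2)]
        phewas = set(rng.choice(len(pool), 8, replace=False).tolist())
        phewas = {pool[i] for i in phewas}
        ehr = {p for p in pool if rng.random() < 0.5}
        per, summary = ehr_pair_concordance(phewas, ehr_pairs=ehr)
        # each pair counted twice across its two phenotypes
        num = sum(pc.n_shared_with_ehr for pc in per)
        den = sum(pc.n_phewas_pairs for pc in per)
        assert summary["overall_percent"] == pytest.approx(100.0 * num / den)

    def test_requires_exactly_one_source(self):
        with pytest.raises(ValueError):
            ehr_pair_concordance([frozenset(("a", "b"))])

    def test_consistency_shared_loci_imply_correlation(self):
        # traits sharing causal loci correlate; concordance high at large n
        shared1 = tuple(f"v{j}" for j in range(0, 10))
        shared2 = tuple(f"v{j}" for j in range(20, 30))
        ones = tuple([1.0] * 10)  # identical effects -> genetic correlation
        specs = [
            PhenotypeSpec(name="a1", heritability=0.5, causal_variant_ids=shared1,
                          effect_sizes=ones),
            PhenotypeSpec(name="a2", heritability=0.5, causal_variant_ids=shared1,
                          effect_sizes=ones),
            PhenotypeSpec(name="b1", heritability=0.5, causal_variant_ids=shared2,
                          effect_sizes=ones),
            PhenotypeSpec(name="b2", heritability=0.5, causal_variant_ids=shared2,
                          effect_sizes=ones),
        ]
        cfg = SimulationConfig(
            n_individuals=10_000, n_variants=40, n_ld_blocks=40, seed=51,
            phenotype_specs=specs,
        )
        gm, table, _ = simulate_cohort(cfg)
        run = run_phewas(gm, table)
        net = build_phenotype_network(extract_cpa(run, {}, 1e-4))
        phewas_pairs = set(map(frozenset, net.edges()))
        assert phewas_pairs  # planted pleiotropy found
        per, summary = ehr_pair_concordance(phewas_pairs, ehr_table=table)
        assert summary["overall_percent"] >= 90.0
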