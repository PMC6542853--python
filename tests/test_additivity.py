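import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import comboseq as cs
from comboseq.additivity import VENN_REGIONS, round_half_up_percent


def make_marginal_sets(n_a=3129, n_b=1794, n_common=800, n_ab=4296, n_overlap=2987):
    """Three gene-id sets realizing given marginal counts.

    |A|, |B|, |A∩B|, |AB| and |AB∩(A∪B)| are the free marginals; the split of
    the combined-treatment overlap across the finer regions is arbitrary.
    """
    ids = [f"g{i:05d}" for i in range(n_a + n_b + n_ab)]
    common = ids[:n_common]
    a_only = ids[n_common : n_common + (n_a - n_common)]
    b_only = ids[n_common + (n_a - n_common) : n_common + (n_a - n_common) + (n_b - n_common)]
    set_a = frozenset(common + a_only)
    set_b = frozenset(common + b_only)
    union = sorted(set_a | set_b)
    fresh = [x for x in ids if x not in set_a and x not in set_b]
    set_ab = frozenset(union[:n_overlap] + fresh[: n_ab - n_overlap])
    return set_a, set_b, set_ab


gene_sets = st.sets(st.integers(min_value=0, max_value=60).map(lambda i: f"g{i}"), max_size=40)


class TestPartitionSets:
    def test_disjoint_inputs_have_empty_intersections(self):
        part = cs.partition_sets({"a"}, {"b"}, {"c"})
        assert part.regions["A_only"] == {"a"}
        assert part.regions["B_only"] == {"b"}
        assert part.regions["AB_only"] == {"c"}
        assert all(
            not part.regions[r] for r in VENN_REGIONS if r not in ("A_only", "B_only", "AB_only")
        )

    def test_identical_inputs_populate_only_triple_region(self):
        part = cs.partition_sets({"x", "y"}, {"x", "y"}, {"x", "y"})
        assert part.regions["A_B_AB"] == {"x", "y"}
        assert sum(len(part.regions[r]) for r in VENN_REGIONS) == 2

    def test_factorial_study_marginals(self):
        # marginals as published for the vitamin-D / Wnt factorial experiment
        set_a, set_b, set_ab = make_marginal_sets()
        counts = cs.partition_sets(set_a, set_b, set_ab).counts()
        assert counts["commonAB"] == 800
        assert counts["A_unshared"] == 2329
        assert counts["B_unshared"] == 994
        assert counts["AB_only"] == 1309
        assert counts["combo_overlap"] == 2987
        assert round_half_up_percent(counts["combo_overlap"], counts["AB_total"]) == 70

    @given(gene_sets, gene_sets, gene_sets)
    def test_regions_disjoint_and_exhaustive(self, a, b, ab):
        part = cs.partition_sets(a, b, ab)
        regions = [part.regions[r] for r in VENN_REGIONS]
        assert sum(len(r) for r in regions) == len(set().union(*regions))
        assert set().union(*regions) == set(a) | set(b) | set(ab)
        assert len(part.commonAB) == len(part.regions["A_B_AB"]) + len(part.regions["A_B_not_AB"])
        assert len(part.combo_overlap) + len(part.regions["AB_only"]) == len(frozenset(ab))


class TestConcordance:
    @pytest.mark.parametrize(
        "a, b, cls",
        [(1.0, 2.0, "both_up"), (-1.0, -0.5, "both_down"),
         (1.0, -1.0, "A_up_B_down"), (-2.0, 0.3, "A_down_B_up")],
    )
    def test_sign_pairs(self, a, b, cls):
        out = cs.classify_concordance({"g"}, {"g": a}, {"g": b})
        assert getattr(out, cls) == {"g"}

    def test_zero_lfc_signals_upstream_inconsistency(self):
        with pytest.raises(cs.ValidationError, match="zero|0"):
            cs.classify_concordance({"g"}, {"g": 0.0}, {"g": 1.0})

    def test_published_class_sizes_round_to_55_45(self):
        # 219 + 217 concordant, 228 + 136 discordant over 800 common genes
        lfcA, lfcB = {}, {}
        sizes = {(1, 1): 219, (-1, -1): 217, (1, -1): 228, (-1, 1): 136}
        i = 0
        for (sa, sb), n in sizes.items():
            for _ in range(n):
                lfcA[f"g{i}"] = float(sa)
                lfcB[f"g{i}"] = float(sb)
                i += 1
        out = cs.classify_concordance(set(lfcA), lfcA, lfcB)
        c = out.counts()
        assert (c["both_up"], c["both_down"], c["A_up_B_down"], c["A_down_B_up"]) == (219, 217, 228, 136)
        assert c["concordant_percent"] == 55  # 436/800 = 54.5, round half up
        assert c["discordant_percent"] == 45  # complement, so the pair sums to 100

    @given(st.dictionaries(st.integers(0, 30).map(str),
                           st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=1))
    def test_classes_partition_common(self, lfc):
        lfcA = {g: a if a != 0 else 0.1 for g, (a, _) in lfc.items()}
        lfcB = {g: b if b != 0 else -0.1 for g, (_, b) in lfc.items()}
        out = cs.classify_concordance(set(lfc), lfcA, lfcB)
        assert out.n == len(lfc)
        assert out.concordant_percent + out.discordant_percent == 100


class TestExpectedAdditive:
    @pytest.mark.parametrize("a, b, want", [(0.0, 2.5, 2.5), (1.3, -1.3, 0.0), (1.5, -0.5, 1.0)])
    def test_sum_of_single_treatment_lfcs(self, a, b, want):
        assert cs.expected_additive_lfc(a, b) == pytest.approx(want)

    def test_non_finite_input_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.expected_additive_lfc(np.nan, 1.0)


class TestFitAdditivity:
    def _series(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))])

    def test_perfect_additivity(self):
        exp = self._series([-2.0, -0.5, 1.0, 2.5])
        fit = cs.fit_additivity(exp, exp, set(exp.index), "union")
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_half_scaling(self):
        exp = self._series([-2.0, 0.5, 1.0, 3.0])
        fit = cs.fit_additivity(0.5 * exp, exp, set(exp.index), "s")
        assert fit.slope == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_r_squared_is_pearson_squared(self):
        rng = np.random.default_rng(1)
        exp = self._series(rng.normal(0, 2, 50))
        obs = exp + rng.normal(0, 0.5, 50)
        fit = cs.fit_additivity(obs, exp, set(exp.index), "s")
        assert fit.r_squared == pytest.approx(fit.pearson_r**2, abs=1e-12)

    def test_zero_variance_expected_rejected(self):
        exp = self._series([1.0, 1.0, 1.0])
        with pytest.raises(cs.ValidationError, match="variance"):
            cs.fit_additivity(exp, exp, set(exp.index), "s")

    def test_too_few_genes_rejected(self):
        exp = self._series([1.0, 2.0])
        with pytest.raises(cs.ValidationError, match=">= 3"):
            cs.fit_additivity(exp, exp, set(exp.index), "s")

    def test_invariant_to_gene_ordering_and_relabeling(self):
        rng = np.random.default_rng(2)
        exp = self._series(rng.normal(0, 2, 30))
        obs = exp * 0.9 + rng.normal(0, 0.3, 30)
        fit1 = cs.fit_additivity(obs, exp, set(exp.index), "s")
        relabel = {g: f"x_{g}" for g in exp.index}
        perm = rng.permutation(30)
        fit2 = cs.fit_additivity(
            obs.iloc[perm].rename(relabel), exp.iloc[perm].rename(relabel),
            {relabel[g] for g in exp.index}, "s",
        )
        assert fit1.slope == pytest.approx(fit2.slope)
        assert fit1.r_squared == pytest.approx(fit2.r_squared)


class TestAttenuation:
    def test_empty_candidate_set(self):
        empty = cs.DEGeneSet("b", 0.05, frozenset())
        res = cs.attenuation(empty, pd.DataFrame(columns=["gene_id", "log2fc", "pvalue"]),
                             pd.DataFrame(columns=["gene_id", "log2fc", "pvalue"]))
        assert res.fraction is None and not res.attenuated

    def test_published_fraction_arithmetic(self):
        # 410 of 1,794 candidates significantly opposed -> 23%
        n, n_att = 1794, 410
        genes = [f"g{i}" for i in range(n)]
        res_b = pd.DataFrame({"gene_id": genes, "log2fc": 1.0, "pvalue": 1e-6})
        p_ab = np.full(n, 0.9)
        lfc_ab = np.full(n, 0.2)
        p_ab[:n_att] = 1e-8
        lfc_ab[:n_att] = -0.5
        res_ab_b = pd.DataFrame({"gene_id": genes, "log2fc": lfc_ab, "pvalue": p_ab})
        out = cs.attenuation(frozenset(genes), res_b, res_ab_b, alpha=0.05)
        assert len(out.attenuated) == n_att
        assert out.counts()["percent"] == 23

    def test_same_sign_significant_genes_not_attenuated(self):
        genes = ["g0", "g1"]
        res_b = pd.DataFrame({"gene_id": genes, "log2fc": [1.0, 1.0], "pvalue": [1e-6] * 2})
        res_ab_b = pd.DataFrame({"gene_id": genes, "log2fc": [0.8, -0.8], "pvalue": [1e-9] * 2})
        out = cs.attenuation(frozenset(genes), res_b, res_ab_b, alpha=0.05)
        assert out.attenuated == frozenset({"g1"})

    def test_missing_pvalues_excluded_and_counted(self):
        genes = ["g0", "g1", "g2"]
        res_b = pd.DataFrame({"gene_id": genes, "log2fc": [1.0] * 3, "pvalue": [1e-6] * 3})
        res_ab_b = pd.DataFrame(
            {"gene_id": genes, "log2fc": [-1.0, -1.0, -1.0], "pvalue": [1e-9, np.nan, 1e-9]}
        )
        out = cs.attenuation(frozenset(genes), res_b, res_ab_b, alpha=0.05)
        assert out.n_excluded_missing == 1
        assert out.candidate_set == frozenset({"g0", "g2"})


class TestSimulationRecovery:
    def test_slope_recovery_across_seeds(self):
        # gamma == 0: union-subset regression should recover slope 1 and
        # intercept 0 in at least 90% of seeds
        ok = 0
        for seed in range(20):
            params = cs.SimulationParams(n_genes=600, seed=1000 + seed)
            _, cm, design = cs.simulate_dataset(params)
            res = cs.NBFactorialModel(cm, design).fit()
            rA = res.contrast("TRT_A", "VEHICLE")
            rB = res.contrast("TRT_B", "VEHICLE")
            rAB = res.contrast("COMBO", "VEHICLE")
            fits = cs.standard_additivity_fits(
                rA, rB, rAB,
                cs.select_de(rA, 0.05), cs.select_de(rB, 0.05), cs.select_de(rAB, 0.05),
            )
            fit = fits["union_singles"]
            if 0.9 <= fit.slope <= 1.1 and -0.1 <= fit.intercept <= 0.1:
                ok += 1
        assert ok >= 18

    def test_interaction_mass_degrades_r_squared(self):
        # heavier interaction terms must strictly reduce the union-subset r^2
        r2 = []
        for gamma_sd in (0.0, 0.5, 1.5):
            vals = []
            for seed in (7, 8, 9):
                params = cs.SimulationParams(n_genes=600, gamma_sd=gamma_sd, seed=seed)
                _, cm, design = cs.simulate_dataset(params)
                res = cs.NBFactorialModel(cm, design).fit()
                rA = res.contrast("TRT_A", "VEHICLE")
                rB = res.contrast("TRT_B", "VEHICLE")
                rAB = res.contrast("COMBO", "VEHICLE")
                fits = cs.standard_additivity_fits(
                    rA, rB, rAB,
                    cs.select_de(rA, 0.05), cs.select_de(rB, 0.05), cs.select_de(rAB, 0.05),
                )
                vals.append(fits["union_singles"].r_squared)
            r2.append(np.mean(vals))
        assert r2[0] > r2[1] > r2[2]
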