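import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oracles import (forward_selection_oracle, ld_closure_clusters_oracle,
                     single_linkage_regions_oracle)
from pqtlkit.config import Thresholds
from pqtlkit.gwas import (DegenerateInputError, ProteinGwas,
                          RankDeficiencyError, assoc_test,
                          classify_cis_trans, clump_pqtls, gwas_scan,
                          joint_model, ld_r2, merge_regions,
                          prepare_phenotype, rint, stepwise_conditional)
from pqtlkit.io import GenotypeMatrix


class TestRint:
    def test_blom_scores_for_three_values(self):
        # Phi^-1 at (2.625/3.25, 0.625/3.25, 1.625/3.25)
        out = rint([3.0, 1.0, 2.0])
        expected = stats.norm.ppf([2.625 / 3.25, 0.625 / 3.25,
                                   1.625 / 3.25])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [0.8694, -0.8694, 0.0], atol=5e-5)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30,
                    unique=True))
    def test_invariant_under_monotone_transform(self, values):
        from hypothesis import assume

        values = np.array(values)
        transformed = np.exp(values / 50.0)
        assume(len(np.unique(transformed)) == len(values))
        np.testing.assert_allclose(rint(values), rint(transformed),
                                   atol=1e-12)

    def test_pair_scores_sum_to_zero(self):
        assert rint([5.0, 9.0]).sum() == pytest.approx(0.0, abs=1e-12)

    def test_ties_get_average_rank(self):
        out = rint([1.0, 1.0, 2.0])
        assert out[0] == out[1] < out[2]

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            rint([2.0, 2.0, 2.0])


class TestPreparePhenotype:
    def _samples(self, n, rng):
        return pd.DataFrame({
            "donor_id": [f"d{i}" for i in range(n)],
            "sex": rng.choice(["F", "M"], n),
            "age": rng.integers(40, 70, n),
            "sample_age": rng.uniform(0, 10, n),
        })

    def test_age_effect_removed(self, rng):
        n = 2000
        samples = self._samples(n, rng)
        levels = pd.Series(
            np.exp(0.05 * samples["age"].to_numpy()
                   + rng.normal(0, 0.3, n)),
            index=samples["donor_id"])
        pheno = prepare_phenotype(levels, samples)
        r = np.corrcoef(pheno.to_numpy(),
                        samples.set_index("donor_id").loc[pheno.index,
                                                          "age"])[0, 1]
        assert abs(r) < 0.02

    def test_unit_variance_and_determinism(self, rng):
        samples = self._samples(300, rng)
        levels = pd.Series(np.exp(rng.normal(0, 1, 300)),
                           index=samples["donor_id"])
        a = prepare_phenotype(levels, samples)
        b = prepare_phenotype(levels, samples)
        pd.testing.assert_series_equal(a, b)
        assert a.std(ddof=0) == pytest.approx(1.0, rel=0.02)

    def test_missing_covariates_dropped(self, rng):
        samples = self._samples(50, rng)
        samples.loc[3, "age"] = np.nan
        levels = pd.Series(np.exp(rng.normal(0, 1, 50)),
                           index=samples["donor_id"])
        with pytest.warns(UserWarning, match="dropped 1 donors"):
            pheno = prepare_phenotype(levels, samples)
        assert "d3" not in pheno.index and len(pheno) == 49


class TestAssocTest:
    def test_orthogonal_dosage_gives_zero_beta_unit_p(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        g = np.array([1.0, 1.0, 0.0, 0.0])
        res = assoc_test(y, g)
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 100).astype(float)
        y = 0.5 * (g - g.mean())
        res = assoc_test(y, g)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.p < 1e-30

    def test_null_pvalues_uniform(self, rng):
        # 10,000 null marginal tests: Kolmogorov distance < 0.02
        n = 200
        y = pd.Series(rng.standard_normal(n),
                      index=[f"d{i}" for i in range(n)])
        g = rng.binomial(2, 0.3, size=(n, 10_000)).astype(float)
        gm = GenotypeMatrix(list(y.index),
                            [f"v{j}" for j in range(10_000)], g)
        scan = gwas_scan(y, gm, Thresholds())
        grid = np.sort(scan["p"].to_numpy())
        ks = np.max(np.abs(grid - np.arange(1, len(grid) + 1) / len(grid)))
        assert ks < 0.02

    def test_scan_matches_assoc_test(self, rng):
        n = 150
        y = pd.Series(rng.standard_normal(n),
                      index=[f"d{i}" for i in range(n)])
        g = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        gm = GenotypeMatrix(list(y.index), [f"v{j}" for j in range(5)], g)
        scan = gwas_scan(y, gm, Thresholds()).set_index("variant_id")
        for j in range(5):
            res = assoc_test(y.to_numpy(), g[:, j])
            assert scan.at[f"v{j}", "beta"] == pytest.approx(res.beta,
                                                             rel=1e-10)
            assert scan.at[f"v{j}", "p"] == pytest.approx(res.p, rel=1e-8)

    def test_collinear_conditioning_rejected(self, rng):
        n = 50
        y = rng.standard_normal(n)
        g = rng.binomial(2, 0.4, n).astype(float)
        cond = np.column_stack([g, 2 - g])
        with pytest.raises(RankDeficiencyError):
            assoc_test(y, rng.binomial(2, 0.3, n).astype(float), cond,
                       conditioning_ids=("c1", "c2"))


def _random_instance(rng, n=150, m=12, n_causal=2):
    # correlated dosages via shared latent factors
    latent = rng.standard_normal((n, 3))
    load = rng.standard_normal((3, m))
    liability = latent @ load + rng.standard_normal((n, m))
    freqs = rng.uniform(0.1, 0.5, m)
    g = np.zeros((n, m))
    for j in range(m):
        t = np.quantile(liability[:, j], 1 - freqs[j])
        g[:, j] = (liability[:, j] > t).astype(float) + \
            rng.binomial(1, freqs[j], n)
    causal = rng.choice(m, size=n_causal, replace=False)
    y = g[:, causal] @ rng.uniform(0.4, 0.8, n_causal) + \
        rng.standard_normal(n)
    ids = [f"v{j:02d}" for j in range(m)]
    pos = (rng.permutation(m) + 1) * 1000
    return y, g, ids, pos


class TestStepwiseConditional:
    def _thresholds(self):
        return Thresholds(genomewide_p=1e-4, candidate_p=0.05)

    def test_empty_candidates_no_signals(self, rng):
        y, g, ids, pos = _random_instance(rng)
        gm = GenotypeMatrix([f"d{i}" for i in range(len(y))], ids, g)
        variants = pd.DataFrame({"variant_id": ids, "pos": pos})
        pheno = pd.Series(y, index=gm.donors)
        out = stepwise_conditional(pheno, gm, [], variants,
                                   self._thresholds())
        assert out == []

    def test_single_causal_yields_single_signal(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            latent = rng.standard_normal(n)
            g = np.column_stack([
                (latent + rng.standard_normal(n) * 0.3 > 0.5).astype(float)
                + (latent + rng.standard_normal(n) * 0.3 > 1.5)
                for _ in range(6)])
            causal = g[:, 2]
            y = 0.5 * causal + rng.standard_normal(n)
            ids = [f"v{j}" for j in range(6)]
            gm = GenotypeMatrix([f"d{i}" for i in range(n)], ids, g)
            variants = pd.DataFrame({"variant_id": ids,
                                     "pos": np.arange(6) * 1000 + 1})
            pheno = pd.Series(y, index=gm.donors)
            scan = gwas_scan(pheno, gm, self._thresholds())
            cands = list(scan.loc[scan["p"] < 0.05, "variant_id"])
            out = stepwise_conditional(pheno, gm, cands, variants,
                                       self._thresholds())
            assert len(out) == 1
            r2 = ld_r2(gm.dosage(out[0].variant_id), causal)
            assert r2 > 0.5  # the signal is the causal variant or a proxy
            hits.append(r2 > 0.8)
        assert sum(hits) >= 18

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_forward_selection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, g, ids, pos = _random_instance(rng, m=10)
        th = self._thresholds()
        gm = GenotypeMatrix([f"d{i}" for i in range(len(y))], ids, g)
        variants = pd.DataFrame({"variant_id": ids, "pos": pos})
        pheno = pd.Series(y, index=gm.donors)
        scan = gwas_scan(pheno, gm, th)
        cands = list(scan.loc[scan["p"] < th.candidate_p, "variant_id"])
        ours = stepwise_conditional(pheno, gm, cands, variants, th)
        oracle = forward_selection_oracle(y, g, ids, list(pos),
                                          th.candidate_p, th.genomewide_p)
        assert [r.variant_id for r in ours] == [o[0] for o in oracle]
        for r, o in zip(ours, oracle):
            assert r.beta == pytest.approx(o[1], rel=1e-8)
            assert r.se == pytest.approx(o[2], rel=1e-8)
            assert r.p == pytest.approx(o[3], rel=1e-6, abs=1e-300)


class TestJointModel:
    def test_single_variant_equals_marginal(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.4 * g + rng.standard_normal(n)
        pheno = pd.Series(y, index=[f"d{i}" for i in range(n)])
        gm = GenotypeMatrix(list(pheno.index), ["v1"], g[:, None])
        marginal = assoc_test(y, g)
        joint = joint_model(pheno, gm, ["v1"], Thresholds())
        assert joint.at[0, "beta_joint"] == pytest.approx(marginal.beta)
        assert joint.at[0, "se_joint"] == pytest.approx(marginal.se)
        assert joint.at[0, "p_joint"] == pytest.approx(marginal.p,
                                                       rel=1e-9,
                                                       abs=1e-300)

    def test_orthogonal_causals_keep_marginal_betas(self, rng):
        n = 3000
        g1 = rng.binomial(2, 0.5, n).astype(float)
        g2 = rng.binomial(2, 0.5, n).astype(float)
        y = 0.3 * g1 - 0.4 * g2 + rng.standard_normal(n)
        pheno = pd.Series(y, index=[f"d{i}" for i in range(n)])
        gm = GenotypeMatrix(list(pheno.index), ["v1", "v2"],
                            np.column_stack([g1, g2]))
        joint = joint_model(pheno, gm, ["v1", "v2"],
                            Thresholds()).set_index("variant_id")
        assert joint.at["v1", "beta_joint"] == pytest.approx(
            assoc_test(y, g1).beta, abs=0.02)
        assert joint.at["v2", "beta_joint"] == pytest.approx(
            assoc_test(y, g2).beta, abs=0.02)

    def test_duplicated_variant_rejected(self, rng):
        pheno = pd.Series(rng.standard_normal(30),
                          index=[f"d{i}" for i in range(30)])
        g = rng.binomial(2, 0.3, 30).astype(float)
        gm = GenotypeMatrix(list(pheno.index), ["v1"], g[:, None])
        with pytest.raises(RankDeficiencyError):
            joint_model(pheno, gm, ["v1", "v1"], Thresholds())


class TestLdR2:
    def test_identical_vectors(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_flip_invariant(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_variants_low_r2(self, rng):
        vals = [ld_r2(rng.binomial(2, 0.3, 2000).astype(float),
                      rng.binomial(2, 0.3, 2000).astype(float))
                for _ in range(20)]
        assert np.median(vals) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(np.ones(10), np.arange(10.0))


def _signals(positions, chrom="chr1", ps=None):
    ps = ps if ps is not None else np.linspace(1e-12, 1e-10,
                                               len(positions))
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions, "p_marginal": ps,
        "discovery_order": np.arange(len(positions)),
    })


class TestMergeRegions:
    def test_within_two_mb_one_region(self, thresholds):
        out = merge_regions(_signals([1_000_000, 2_900_000]), thresholds)
        assert out["region_id"].nunique() == 1

    def test_beyond_two_mb_two_regions(self, thresholds):
        out = merge_regions(_signals([1_000_000, 3_100_000]), thresholds)
        assert out["region_id"].nunique() == 2

    def test_transitive_chain(self, thresholds):
        out = merge_regions(_signals([1, 1_500_001, 3_000_001]),
                            thresholds)
        assert out["region_id"].nunique() == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_single_linkage_oracle(self, seed, thresholds):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.integers(1, 30_000_000, 15))
        out = merge_regions(_signals(list(pos)), thresholds)
        oracle = single_linkage_regions_oracle(list(pos),
                                               thresholds.region_merge_bp)
        ours = out.sort_values("pos")["region_id"].to_numpy()
        theirs = np.array(oracle)[np.argsort(pos, kind="stable")]
        # same partition up to relabelling
        mapping = {}
        for a, b in zip(ours, theirs):
            assert mapping.setdefault(a, b) == b

    def test_mhc_is_single_region(self, thresholds):
        out = merge_regions(
            _signals([25_600_000, 33_900_000], chrom="chr6"), thresholds)
        assert out["region_id"].nunique() == 1

    def test_sentinel_is_smallest_marginal_p(self, thresholds):
        out = merge_regions(
            _signals([100, 1000, 2000], ps=[1e-10, 1e-30, 1e-12]),
            thresholds)
        assert out.loc[out["rank"] == 1, "variant_id"].item() == "v1"


class TestClassifyCisTrans:
    def test_at_tss_is_cis(self, thresholds):
        assert classify_cis_trans("chr1", 500, "chr1", 500,
                                  thresholds) == "cis"

    def test_exactly_one_mb_inclusive(self, thresholds):
        assert classify_cis_trans("chr1", 1_000_001, "chr1", 1,
                                  thresholds) == "cis"
        assert classify_cis_trans("chr1", 1_000_002, "chr1", 1,
                                  thresholds) == "trans"

    def test_other_chromosome_is_trans(self, thresholds):
        assert classify_cis_trans("chr2", 500, "chr1", 500,
                                  thresholds) == "trans"

    def test_missing_tss_unclassifiable(self, thresholds):
        assert classify_cis_trans("chr1", 500, None, None,
                                  thresholds) == "unclassifiable"


class TestClumpPqtls:
    def _frame(self, variant_ids, targets, ps, positions):
        return pd.DataFrame({
            "variant_id": variant_ids, "target_id": targets,
            "p_marginal": ps, "pos": positions,
            "chrom": "chr1", "cis_trans": "trans",
        })

    def test_shared_variant_two_assays_one_cluster(self, rng, thresholds):
        g = rng.binomial(2, 0.3, 500).astype(float)
        gm = GenotypeMatrix([f"d{i}" for i in range(500)], ["v1"],
                            g[:, None])
        signals = self._frame(["v1", "v1"], ["P1", "P2"],
                              [1e-20, 1e-15], [100, 100])
        out = clump_pqtls(signals, gm, thresholds)
        assert out["cluster_id"].nunique() == 1
        assert out["cluster_protein_count"].iloc[0] == 2

    def test_nonspecific_flag_strictly_greater_than_ten(self, rng,
                                                        thresholds):
        g = rng.binomial(2, 0.3, 500).astype(float)
        gm = GenotypeMatrix([f"d{i}" for i in range(500)], ["v1"],
                            g[:, None])
        for count, expect in ((10, False), (11, True)):
            signals = self._frame(["v1"] * count,
                                  [f"P{i}" for i in range(count)],
                                  [1e-20] * count, [100] * count)
            out = clump_pqtls(signals, gm, thresholds)
            assert bool(out["non_specific"].iloc[0]) is expect

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_when_unambiguous(self, seed,
                                                         thresholds):
        rng = np.random.default_rng(seed)
        n, m = 400, 8
        latent = rng.standard_normal(n)
        g = np.column_stack([
            ((latent if j < 4 else rng.standard_normal(n))
             + 0.1 * rng.standard_normal(n) > 0.5).astype(float)
            for j in range(m)])
        ids = [f"v{j}" for j in range(m)]
        gm = GenotypeMatrix([f"d{i}" for i in range(n)], ids, g)
        signals = self._frame(ids, [f"P{j}" for j in range(m)],
                              list(rng.uniform(1e-30, 1e-10, m)),
                              list(np.arange(m) * 100))
        ours = clump_pqtls(signals, gm, thresholds)
        closure = ld_closure_clusters_oracle(g, thresholds.ld_high_r2)
        # when greedy and closure agree on the partition sizes, require
        # identical partitions; otherwise the disagreement is reported
        ours_sets = {frozenset(grp["variant_id"])
                     for _, grp in ours.groupby("cluster_id")}
        closure_sets = {}
        for vid, lab in zip(ids, closure):
            closure_sets.setdefault(lab, set()).add(vid)
        closure_sets = {frozenset(s) for s in closure_sets.values()}
        if len(ours_sets) == len(closure_sets):
            assert ours_sets == closure_sets


class TestModelObject:
    def test_fit_recovers_planted_cis_signal(self, small_cohort):
        truth = small_cohort.ledger.cis_effects.set_index("target_id")
        # pick the largest planted effect for power at n=800
        target = truth["beta"].abs().idxmax()
        assay = small_cohort.panel[
            (small_cohort.panel["target_id"] == target) &
            (small_cohort.panel["platform"] == "B")]["assay_id"].iloc[0]
        res = ProteinGwas.from_cohort(small_cohort, assay).fit()
        assert res.n_signals >= 1
        sent = res.sentinels.iloc[0]
        true_vid = truth.loc[target, "variant_id"]
        r2 = 1.0 if sent["variant_id"] == true_vid else ld_r2(
            small_cohort.genotypes.dosage(sent["variant_id"]),
            small_cohort.genotypes.dosage(true_vid))
        assert r2 > 0.8
        assert sent["cis_trans"] == "cis"
        assert "pQTL scan" in res.summary()

    def test_one_sentinel_per_region(self, small_cohort):
        from pqtlkit.gwas import map_platform_pqtls

        signals = map_platform_pqtls(small_cohort, "A")
        if len(signals):
            counts = signals.groupby(["assay_id", "region_id"])["rank"] \
                .apply(lambda r: (r == 1).sum())
            assert (counts == 1).all()
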