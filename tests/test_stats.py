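"""Correlation primitives, Hunter-Schmidt meta-analysis, permutation tests."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from netinflux.stats import (
    ModelData,
    between_model_influence_correlation,
    meta_correlation,
    model_correlation,
    overlap_randomization,
    partial_correlation,
    permutation_test,
    permute_protein_covariates,
    randomization_quantiles,
    residual_permutation_test,
)
from netinflux.stats_core import (
    ConstantInputError,
    ModelCorrelation,
    hunter_schmidt_meta,
    partial_correlation_vectors,
    rank_biserial,
    spearman,
)
from netinflux.synth import PopulationSpec, make_meta_population


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 100, 1000, 10000]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y) == pytest.approx(spearmanr(x, y)[0], abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ConstantInputError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def brute_force_rank_biserial(x, g):
    """Direct pair-counting oracle: P(x1 > x0) - P(x1 < x0)."""
    x = np.asarray(x, float)
    g = np.asarray(g, bool)
    x1, x0 = x[g], x[~g]
    gt = sum(1 for a in x1 for b in x0 if a > b)
    lt = sum(1 for a in x1 for b in x0 if a < b)
    return (gt - lt) / (len(x1) * len(x0))


class TestRankBiserial:
    def test_complete_separation(self):
        assert rank_biserial([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == pytest.approx(1.0)

    def test_symmetric_mixture_is_zero(self):
        assert rank_biserial([1, 2, 3, 4], [0, 1, 1, 0]) == pytest.approx(0.0)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(6, 15))
            x = rng.integers(0, 4, n).astype(float)
            g = rng.integers(0, 2, n)
            if g.sum() in (0, n):
                continue
            assert rank_biserial(x, g) == pytest.approx(
                brute_force_rank_biserial(x, g), abs=1e-12
            )

    def test_nonbinary_group_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            rank_biserial([1.0, 2.0, 3.0], [0, 1, 2])


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r, _, _ = partial_correlation_vectors(x, y, np.empty((20, 0)))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_common_cause_removed(self):
        """x and y driven only by z have (near-)zero partial correlation given z."""
        rng = np.random.default_rng(5)
        z = rng.standard_normal(2000)
        x = z + 0.1 * rng.standard_normal(2000)
        y = z + 0.1 * rng.standard_normal(2000)
        r_raw = np.corrcoef(x, y)[0, 1]
        r_part, _, _ = partial_correlation_vectors(x, y, z.reshape(-1, 1))
        assert r_raw > 0.9
        assert abs(r_part) < 0.1

    def test_exact_linear_dependence_rejected(self):
        z = np.arange(10.0)
        with pytest.raises(ConstantInputError):
            partial_correlation_vectors(2 * z + 1, z + np.random.default_rng(0).standard_normal(10), z.reshape(-1, 1))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            partial_correlation_vectors(
                np.arange(4.0), np.arange(4.0), np.ones((4, 2))
            )


class TestHunterSchmidt:
    def test_weighted_mean_hand_computed(self):
        # (10*0.2 + 30*(-0.4)) / 40 = -0.25
        corrs = [
            ModelCorrelation("m1", ("a", "b"), 0.2, 10),
            ModelCorrelation("m2", ("a", "b"), -0.4, 30),
        ]
        meta = hunter_schmidt_meta(corrs)
        assert meta.rho0 == pytest.approx(-0.25, abs=1e-14)
        assert meta.k == 2

    def test_equal_n_is_plain_mean(self):
        corrs = [
            ModelCorrelation("m1", ("a", "b"), 0.1, 20),
            ModelCorrelation("m2", ("a", "b"), 0.5, 20),
            ModelCorrelation("m3", ("a", "b"), -0.3, 20),
        ]
        assert hunter_schmidt_meta(corrs).rho0 == pytest.approx(0.1, abs=1e-14)

    def test_sampling_variance_single_study(self):
        # n=10, r=0: sigma_e^2 = (1-0)^2 * 10/9 / 10 = 1/9
        meta = hunter_schmidt_meta([ModelCorrelation("m", ("a", "b"), 0.0, 10)])
        assert meta.sigma_e_sq == pytest.approx(1 / 9, abs=1e-14)
        assert meta.sigma_r_sq == 0.0
        assert meta.sigma_rho == 0.0  # truncated at zero

    def test_sampling_variance_decreases_with_n(self):
        m_small = hunter_schmidt_meta([ModelCorrelation("m", ("a", "b"), 0.3, 10)])
        m_big = hunter_schmidt_meta([ModelCorrelation("m", ("a", "b"), 0.3, 100)])
        assert m_big.sigma_e_sq < m_small.sigma_e_sq

    def test_ci_symmetric_about_rho0(self):
        corrs = [
            ModelCorrelation("m1", ("a", "b"), 0.2, 15),
            ModelCorrelation("m2", ("a", "b"), -0.1, 25),
        ]
        meta = hunter_schmidt_meta(corrs)
        lo, hi = meta.ci95
        assert (lo + hi) / 2 == pytest.approx(meta.rho0, abs=1e-12)
        assert hi - meta.rho0 == pytest.approx(1.96 * meta.se, abs=1e-12)

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            hunter_schmidt_meta(
                [
                    ModelCorrelation("m1", ("a", "b"), 0.2, 10),
                    ModelCorrelation("m2", ("a", "c"), 0.2, 10),
                ]
            )

    def test_table_style_display(self):
        corrs = [
            ModelCorrelation("m1", ("omega", "D"), -0.2, 50),
            ModelCorrelation("m2", ("omega", "D"), -0.3, 50),
        ]
        s = str(hunter_schmidt_meta(corrs))
        assert s.startswith("-0.25 (")


def _toy_model(seed=0, n_prot=12, rho=-0.6):
    """One synthetic ModelData with a planted omega/D rank correlation."""
    rng = np.random.default_rng(seed)
    doms_per = rng.integers(1, 4, n_prot)
    prot = np.repeat([f"P{i}" for i in range(n_prot)], doms_per)
    n = len(prot)
    z = rng.standard_normal(n)
    e = rng.standard_normal(n)
    omega = np.exp(0.3 * z)
    d_vals = np.exp(rho * z + np.sqrt(1 - rho**2) * e)
    prot_x = {f"P{i}": float(np.exp(rng.standard_normal())) for i in range(n_prot)}
    prot_e = {f"P{i}": int(rng.random() < 0.3) for i in range(n_prot)}
    table = pd.DataFrame(
        {
            "domain_id": [f"d{j}" for j in range(n)],
            "protein_id": prot,
            "omega": omega,
            "D": d_vals,
            "X": [prot_x[p] for p in prot],
            "E": [prot_e[p] for p in prot],
        }
    )
    kappa = pd.Series(
        np.exp(rng.standard_normal(2 * n)), index=[f"k{j}" for j in range(2 * n)]
    )
    from netinflux.annotations import DomainAnnotation

    rows = []
    for j in range(n):
        rows.append({"protein_id": prot[j], "domain_id": f"d{j}", "param_id": f"k{2 * j}"})
        rows.append({"protein_id": prot[j], "domain_id": f"d{j}", "param_id": f"k{2 * j + 1}"})
    return ModelData(f"toy{seed}", table, kappa, DomainAnnotation(pd.DataFrame(rows)))


class TestModelCorrelation:
    def test_spearman_route(self):
        md = _toy_model(0)
        mc = model_correlation(md, ("omega", "D"))
        assert mc.r == pytest.approx(
            spearmanr(md.table["omega"], md.table["D"])[0], abs=1e-12
        )
        assert mc.n == len(md.table)

    def test_binary_route_uses_rank_biserial(self):
        md = _toy_model(1)
        mc = model_correlation(md, ("D", "E"))
        assert mc.r == pytest.approx(
            rank_biserial(md.table["D"].to_numpy(), md.table["E"].to_numpy()), abs=1e-12
        )

    def test_listwise_deletion(self):
        md = _toy_model(2)
        table = md.table.copy()
        table.loc[0, "omega"] = np.nan
        mc = model_correlation(ModelData("m", table), ("omega", "D"))
        assert mc.n == len(table) - 1

    def test_meta_combines_models(self):
        records = {f"m{i}": _toy_model(i).table for i in range(5)}
        meta, corrs = meta_correlation(records, ("omega", "D"))
        assert meta.k == 5
        assert meta.rho0 < -0.3  # planted correlation is -0.6


class TestPermutationSchemes:
    def test_protein_level_permutation_preserves_constancy(self):
        md = _toy_model(3)
        rng = np.random.default_rng(0)
        perm = permute_protein_covariates(md, rng)
        for col in ("X", "E"):
            assert perm.table.groupby("protein_id")[col].nunique().max() == 1
            # multiset of per-protein values preserved
            assert sorted(perm.table.groupby("protein_id")[col].first()) == sorted(
                md.table.groupby("protein_id")[col].first()
            )

    def test_domain_level_null_centred_at_zero(self):
        md = _toy_model(4)
        res = permutation_test({md.model_id: md}, ("omega", "D"), "domain_level", n_perm=2000, seed=0)
        assert abs(np.mean(res.null)) < 0.05
        assert res.n_perm == 2000

    def test_planted_effect_detected(self):
        records = [_toy_model(i, rho=-0.6) for i in range(6)]
        res = permutation_test(records, ("omega", "D"), "domain_level", n_perm=1000, seed=1)
        assert res.observed < -0.3
        assert res.pvalue <= 0.01

    def test_param_influence_needs_kappa(self):
        md = _toy_model(5)
        bare = ModelData(md.model_id, md.table)
        with pytest.raises(ValueError, match="kappa"):
            permutation_test([bare], ("omega", "D"), "param_influence", n_perm=200, seed=0)

    def test_param_influence_runs_and_is_calibrated(self):
        """Permuting kappa then rebuilding D gives a null centred at zero."""
        md = _toy_model(6, rho=0.0)
        res = permutation_test([md], ("omega", "D"), "param_influence", n_perm=1000, seed=0)
        assert abs(np.mean(res.null)) < 0.1
        assert res.pvalue > 0.01  # no planted effect

    def test_protein_level_scheme_on_binary(self):
        records = [_toy_model(i) for i in range(4)]
        res = permutation_test(records, ("D", "E"), "protein_level", n_perm=500, seed=0)
        assert res.n_perm == 500
        assert -1 <= res.observed <= 1

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown permutation scheme"):
            permutation_test([_toy_model(0)], ("omega", "D"), "bogus", n_perm=200)

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test([_toy_model(0)], ("omega", "D"), "domain_level", n_perm=50)

    def test_pvalue_floor_convention(self):
        records = [_toy_model(i, rho=-0.9) for i in range(8)]
        res = permutation_test(records, ("omega", "D"), "domain_level", n_perm=200, seed=0)
        if res.below_resolution:
            assert res.pvalue == pytest.approx(1 / 200)
            assert res.pvalue_str.startswith("<")

    def test_seed_reproducibility(self):
        md = _toy_model(7)
        r1 = permutation_test([md], ("omega", "D"), "domain_level", n_perm=300, seed=5)
        r2 = permutation_test([md], ("omega", "D"), "domain_level", n_perm=300, seed=5)
        np.testing.assert_array_equal(r1.null, r2.null)
        r3 = permutation_test([md], ("omega", "D"), "domain_level", n_perm=300, seed=6)
        assert not np.array_equal(r1.null, r3.null)

    def test_vectorized_null_matches_loop(self):
        """The vectorized domain-level null equals per-permutation recomputation."""
        from netinflux.stats import _model_rng, _null_for_model

        md = _toy_model(8)
        null, _ = _null_for_model(md, ("omega", "D"), "domain_level", 50, seed=9)
        rng = _model_rng(9, md.model_id, "domain_level")
        omega = md.table["omega"].to_numpy(float)
        d = md.table["D"].to_numpy(float)
        perms = rng.permuted(np.tile(omega, (50, 1)), axis=1)
        loop = np.array([spearman(perms[i], d) for i in range(50)])
        np.testing.assert_allclose(null, loop, atol=1e-12)


class TestResidualPermutation:
    def test_matches_partial_correlation_observed(self):
        records = [_toy_model(i) for i in range(3)]
        res = residual_permutation_test(records, ("omega", "D"), ["X"], n_perm=200, seed=0)
        corrs = [partial_correlation(md, ("omega", "D"), ["X"]) for md in records]
        expected = hunter_schmidt_meta(corrs).rho0
        assert res.observed == pytest.approx(expected, abs=1e-12)

    def test_null_centred_and_calibrated(self):
        records = [_toy_model(i, rho=0.0) for i in range(5)]
        res = residual_permutation_test(records, ("omega", "D"), ["X"], n_perm=1000, seed=2)
        assert abs(np.mean(res.null)) < 0.05
        assert res.pvalue > 0.01


class TestBetweenModels:
    def test_hand_computed_weighted_mean(self):
        d1 = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        d2 = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))  # r=1, overlap 5
        d3 = pd.Series([4.0, 3, 2, 1], index=list("abcd"))  # r=-1 with both, overlap 4
        mean, pairs = between_model_influence_correlation({"m1": d1, "m2": d2, "m3": d3})
        # (5*1 + 4*(-1) + 4*(-1)) / 13
        assert mean == pytest.approx(-3 / 13, abs=1e-12)
        assert len(pairs) == 3

    def test_min_overlap_exclusion(self):
        d1 = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        d2 = pd.Series([1.0, 2, 3], index=list("abc"))  # overlap 3 < 4: excluded
        with pytest.raises(ValueError, match="no model pair"):
            between_model_influence_correlation({"m1": d1, "m2": d2})

    def test_synthetic_overlap_population(self):
        tabs = make_meta_population(
            PopulationSpec(k_networks=6, overlap_fraction=0.5, seed=2)
        )
        infl = {m: t.set_index("domain_id")["D"] for m, t in tabs.items()}
        mean, pairs = between_model_influence_correlation(infl)
        assert len(pairs) >= 3
        assert mean > 0  # shared domains share part of their influence latent


class TestOverlapRandomization:
    def test_no_shared_domains_is_identity(self):
        records = {f"m{i}": _toy_model(i).table.assign(
            domain_id=lambda t, i=i: [f"m{i}_{d}" for d in t["domain_id"]]
        ) for i in range(3)}
        base = permutation_test(records, ("omega", "D"), "domain_level", n_perm=300, seed=0)
        df = overlap_randomization(
            records, ("omega", "D"), n_rep=3, n_perm=300, seed=0
        )
        assert len(df) == 3
        assert np.allclose(df["rho0"], base.observed)

    def test_shared_domain_retained_in_exactly_one_model(self):
        tabs = make_meta_population(
            PopulationSpec(k_networks=4, overlap_fraction=0.5, seed=3)
        )
        df = overlap_randomization(tabs, ("omega", "D"), n_rep=5, n_perm=200, seed=1)
        assert len(df) == 5
        q = randomization_quantiles(df)
        med, lo, hi = q["rho0"]
        assert lo <= med <= hi
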