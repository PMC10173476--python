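"""TMM factors, dispersion estimation, the NB likelihood-ratio test and the
midparent-value TE test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from plureval.core_io import PipelineConfig, ValidationError
from plureval.normalize_de import (
    bh_adjust,
    build_mpv_libraries,
    build_normalization_groups,
    classify_degs,
    de_test,
    estimate_dispersion,
    group_de,
    te_mpv_de,
    tmm_factors,
)
from plureval.preprocess import split_by_subgenome
from plureval.simulate import SimulationConfig, simulate_experiment

from conftest import make_table


# ---------------------------------------------------------------------------
# independent step-by-step TMM reference (the published recipe, written
# directly from its definition rather than reusing the library code path)
# ---------------------------------------------------------------------------


def reference_tmm(counts: np.ndarray) -> np.ndarray:
    sizes = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, j] / sizes[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        obs, refc = counts[:, j], counts[:, ref]
        pos = (obs > 0) & (refc > 0)
        o, r = obs[pos] / sizes[j], refc[pos] / sizes[ref]
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        w = (sizes[j] - obs[pos]) / (sizes[j] * obs[pos]) + (
            sizes[ref] - refc[pos]
        ) / (sizes[ref] * refc[pos])
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        lo_l, lo_s = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        hi_l, hi_s = n + 1 - lo_l, n + 1 - lo_s
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        factors.append(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def _df(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"s{j}" for j in range(arr.shape[1])])


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        y = _df([[10, 10], [20, 20], [5, 5], [80, 80], [1, 1]])
        np.testing.assert_allclose(tmm_factors(y), 1.0, atol=1e-12)

    def test_pure_depth_scaling_gives_unit_factors(self):
        base = np.array([[10.0], [20.0], [5.0], [80.0], [1.0]])
        y = _df(np.hstack([base, 3 * base]))
        np.testing.assert_allclose(tmm_factors(y), 1.0, atol=1e-9)

    def test_five_gene_toy_matches_stepwise_reference(self):
        y = np.array(
            [[100.0, 110.0], [200.0, 190.0], [300.0, 310.0], [400.0, 20000.0], [500.0, 520.0]]
        )
        np.testing.assert_allclose(tmm_factors(_df(y)), reference_tmm(y), atol=1e-9)

    def test_five_gene_toy_matches_edger_reference_values(self):
        # reference values computed independently with edgeR::calcNormFactors
        # (method="TMM") on this exact matrix
        y = np.array(
            [[100.0, 110.0], [200.0, 190.0], [300.0, 310.0], [400.0, 20000.0], [500.0, 520.0]]
        )
        np.testing.assert_allclose(
            tmm_factors(_df(y)), [3.673654424, 0.272208511], atol=1e-8
        )

    def test_thirty_gene_toy_matches_edger_reference_values(self):
        rng = np.random.default_rng(42)
        m = rng.integers(1, 500, size=(30, 3)).astype(float)
        m[3, 0] = 9000.0
        np.testing.assert_allclose(
            tmm_factors(_df(m)), [0.718580071, 1.259370204, 1.105023255], atol=1e-8
        )

    def test_random_matrices_match_stepwise_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.negative_binomial(3, 0.02, size=(150, 5)).astype(float) + rng.integers(
                0, 2, size=(150, 5)
            )
            np.testing.assert_allclose(tmm_factors(_df(y)), reference_tmm(y), atol=1e-9)

    def test_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(3)
        y = _df(rng.integers(0, 300, size=(100, 6)))
        f = tmm_factors(y)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_normalized_expression(self):
        # Multiplying one library by a constant must leave normalized
        # expression essentially unchanged. The invariance is not exact
        # because the trimmed mean uses count-level precision weights (the
        # canonical TMM behaves identically); the residual is far below any
        # biologically meaningful fold change.
        rng = np.random.default_rng(4)
        mu = rng.uniform(20, 500, size=200)
        lam = rng.gamma(1 / 0.05, 0.05 * mu[:, None] * np.ones((200, 4)))
        y = rng.poisson(lam).astype(float)
        f1 = tmm_factors(_df(y))
        sizes1 = y.sum(axis=0) * f1.to_numpy()
        y2 = y.copy()
        y2[:, 1] *= 7.0
        f2 = tmm_factors(_df(y2))
        sizes2 = y2.sum(axis=0) * f2.to_numpy()
        np.testing.assert_allclose(y / sizes1, y2 / sizes2, rtol=0.01)

    def test_disjoint_library_rejected(self):
        y = _df([[5, 0], [6, 0], [0, 4], [0, 9]])
        with pytest.raises(ValidationError, match="no expressed features"):
            tmm_factors(y)


class TestDispersion:
    def _estimate(self, y, phi_label="synthetic"):
        values = _df(y)
        cond = pd.Series(["c"] * values.shape[1], index=values.columns)
        sizes = pd.Series(1.0, index=values.columns)
        return estimate_dispersion(values, sizes, cond)

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100.0, size=(2000, 10))
        disp = self._estimate(y)
        assert np.median(disp) <= 0.05

    def test_known_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        lam = rng.gamma(1 / 0.2, 0.2 * 100.0, size=(2000, 5))
        y = rng.poisson(lam)
        disp = self._estimate(y)
        assert 0.1 <= disp.attrs["common"] <= 0.3

    def test_constant_feature_floors(self):
        y = np.vstack([np.full(6, 50.0), np.random.default_rng(2).poisson(50, (50, 6))])
        disp = self._estimate(y)
        assert disp.iloc[0] < 0.05

    def test_single_replicate_falls_back_with_common(self):
        values = _df([[5.0, 9.0], [1.0, 2.0]])
        cond = pd.Series(["a", "b"], index=values.columns)
        sizes = pd.Series(1.0, index=values.columns)
        disp = estimate_dispersion(values, sizes, cond)
        assert (disp > 0).all()


def _nb_loglik_scalar(y, mu, phi):
    r = 1.0 / phi
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(np.where(y > 0, mu / (r + mu), 1.0))
    )


class TestDeTest:
    def _run(self, y, n1, n2, phi=0.05, config=None):
        values = _df(y)
        cond = pd.Series(["synthetic"] * n1 + ["parent"] * n2, index=values.columns)
        sizes = pd.Series(1e6, index=values.columns)
        disp = pd.Series(phi, index=values.index)
        return de_test(values, sizes, cond, disp, config or PipelineConfig())

    def test_identical_columns_yield_zero_fold_change(self):
        y = np.tile([[20.0], [7.0], [120.0]], (1, 6))
        rec = self._run(y, 3, 3)
        np.testing.assert_allclose(rec["log2fc"], 0.0, atol=1e-8)
        assert not rec["significant"].any()

    def test_sixteen_fold_change_is_significant(self):
        # group means 160 vs 10 at phi=0.05, n=3+3; cross-check the LRT
        # statistic with a direct likelihood evaluation at the fitted means
        y = np.array([[160.0, 158.0, 162.0, 10.0, 11.0, 9.0]])
        rec = self._run(y, 3, 3)
        assert rec["significant"].iloc[0]
        assert rec["direction"].iloc[0] == "up"
        assert rec["log2fc"].iloc[0] == pytest.approx(4.0, abs=0.1)
        row = y[0]
        mu_alt = np.r_[np.full(3, row[:3].mean()), np.full(3, row[3:].mean())]
        mu_null = np.full(6, row.mean())
        lrt = 2 * (_nb_loglik_scalar(row, mu_alt, 0.05) - _nb_loglik_scalar(row, mu_null, 0.05))
        assert lrt > stats.chi2.isf(1e-6, 1)
        # p refers the signed LRT root to t with residual + prior df (4 + 10)
        assert rec["pvalue"].iloc[0] == pytest.approx(
            2 * stats.t.sf(np.sqrt(lrt), df=14), rel=0.05
        )

    def test_null_simulation_yields_no_degs(self):
        rng = np.random.default_rng(5)
        lam = rng.gamma(1 / 0.1, 0.1 * 100.0, size=(2000, 6))
        y = rng.poisson(lam)
        values = _df(y)
        cond = pd.Series(["synthetic"] * 3 + ["parent"] * 3, index=values.columns)
        sizes = pd.Series(1.0, index=values.columns)
        disp = estimate_dispersion(values, sizes, cond)
        rec = de_test(values, sizes, cond, disp)
        assert rec["significant"].sum() == 0

    def test_empty_contrast_side_rejected(self):
        with pytest.raises(ValidationError, match="empty contrast"):
            self._run(np.ones((2, 3)), 3, 0)


class TestBH:
    def test_monotone_in_sorted_pvalues(self):
        rng = np.random.default_rng(6)
        p = pd.Series(rng.uniform(size=500), index=[f"g{i}" for i in range(500)])
        fdr = bh_adjust(p)
        order = np.argsort(p.to_numpy(), kind="stable")
        assert (np.diff(fdr.to_numpy()[order]) >= -1e-12).all()
        assert fdr.max() <= 1.0

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(7)
        p = pd.Series(rng.uniform(size=100), index=[f"g{i}" for i in range(100)])
        np.testing.assert_allclose(
            bh_adjust(p).to_numpy(), stats.false_discovery_control(p.to_numpy(), method="bh")
        )


class TestClassifyDegs:
    @pytest.mark.parametrize(
        "fdr,log2fc,expect",
        [(0.005, 2.0, "up"), (0.005, 1.0, "none"), (0.02, 3.0, "none"), (0.005, -2.0, "down")],
    )
    def test_threshold_logic(self, fdr, log2fc, expect):
        cfg = PipelineConfig()
        sig = fdr < cfg.fdr_max and abs(log2fc) > cfg.min_abs_log2fc
        rec = pd.DataFrame(
            {
                "subgenome": ["D"],
                "log2fc": [log2fc],
                "pvalue": [fdr],
                "fdr": [fdr],
                "significant": [sig],
                "direction": ["up" if sig and log2fc > 0 else "down" if sig else "none"],
            },
            index=pd.Index(["g1"], name="feature_id"),
        )
        summary = classify_degs(rec)
        if expect == "none":
            assert summary.to_numpy().sum() == 0
        else:
            assert summary.loc["D", expect] == 1


class TestGroups:
    def _dataset(self, genotypes, seed=0):
        cfg = SimulationConfig(
            n_triads=150, rng_seed=seed, mismatch_rate=0.0, synthetic_genotypes=genotypes,
            replicates={"diploid_parent": 2, "tetraploid_parent": 2, "synthetic": 2},
        )
        table, triads, truth = simulate_experiment(cfg)
        roles = table.samples["role"]
        dip = table.subset_samples(table.samples.index[roles == "diploid_parent"])
        tet = table.subset_samples(table.samples.index[roles == "tetraploid_parent"])
        syn = table.subset_samples(table.samples.index[roles == "synthetic"])
        ab, d = split_by_subgenome(syn)
        return ab, d, dip, tet

    def test_shared_parents_give_two_groups(self):
        ab, d, dip, tet = self._dataset(("Lx109", "E109xL"))
        groups = build_normalization_groups(ab, d, dip, tet)
        assert len(groups) == 2
        assert {g.partition for g in groups} == {"AB", "D"}
        for g in groups:
            assert set(g.synthetic_genotypes) == {"E109xL", "Lx109"}

    def test_group_factors_have_unit_geometric_mean(self):
        ab, d, dip, tet = self._dataset(("Lx109",))
        for g in build_normalization_groups(ab, d, dip, tet):
            assert np.exp(np.mean(np.log(g.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_zero_rows_removed_after_normalization(self):
        ab, d, dip, tet = self._dataset(("Lx109",))
        for g in build_normalization_groups(ab, d, dip, tet):
            assert (g.table.values.sum(axis=1) > 0).all()

    def test_missing_parent_assignment_rejected(self):
        ab, d, dip, tet = self._dataset(("Lx109",))
        with pytest.raises(ValidationError, match="no parent assignment"):
            build_normalization_groups(ab, d, dip, tet, parentage={})


class TestMpv:
    def test_printed_formula(self):
        dip = pd.DataFrame({"d1": [300.0]}, index=["fam1"])
        tet = pd.DataFrame({"t1": [600.0]}, index=["fam1"])
        mpv = build_mpv_libraries(dip, tet)
        assert mpv.iloc[0, 0] == pytest.approx(500.0)

    def test_all_replicate_combinations(self):
        dip = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["d1", "d2"])
        tet = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=["t1", "t2", "t3"])
        assert build_mpv_libraries(dip, tet).shape == (3, 6)

    def test_zero_parents_give_zero_mpv(self):
        dip = pd.DataFrame({"d1": [0.0]}, index=["fam1"])
        tet = pd.DataFrame({"t1": [0.0]}, index=["fam1"])
        assert build_mpv_libraries(dip, tet).iloc[0, 0] == 0.0

    def test_empty_replicates_rejected(self):
        dip = pd.DataFrame(index=["fam1"])
        tet = pd.DataFrame({"t1": [1.0]}, index=["fam1"])
        with pytest.raises(ValidationError):
            build_mpv_libraries(dip, tet)

    def test_identical_synthetic_and_mpv_not_significant(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(100, 1000, size=12)
        mpv = pd.DataFrame({f"m{i}": base for i in range(4)}, index=[f"f{i}" for i in range(12)])
        syn = pd.DataFrame({f"s{i}": base for i in range(3)}, index=mpv.index)
        rec = te_mpv_de(syn, mpv)
        assert rec["significant"].sum() == 0
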