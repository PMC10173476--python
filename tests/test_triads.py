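"""Homoeolog-bias triads: contributions, classification, movement, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plureval.core_io import PipelineConfig, TriadTable, ValidationError
from plureval.simulate import SimulationConfig, simulate_experiment
from plureval.preprocess import (
    combine_parents_in_silico,
    normalize_expression,
)
from plureval.triads import (
    CENTROIDS,
    bias_correlation,
    bias_de_association,
    classify_triads,
    eigen_distance,
    triad_contributions,
    triad_movement,
    triad_states,
)

from conftest import make_table


def brute_force_category(point) -> str:
    """Nearest-of-7 oracle: explicit loop over centroids in fixed order."""
    best_name, best_d = None, np.inf
    for name, c in CENTROIDS:
        d = np.sqrt(sum((p - q) ** 2 for p, q in zip(point, c)))
        if d < best_d:
            best_name, best_d = name, d
    return best_name


def states_df(points):
    df = pd.DataFrame(points, columns=["A", "B", "D"],
                      index=[f"t{i}" for i in range(len(points))])
    df["total_rpm"] = 10.0
    return df


def _rpm_table(vals, subgenomes):
    t = make_table(vals, subgenomes=subgenomes)
    t.unit = "rpm"
    return t


def _triad_table(n):
    return TriadTable(
        pd.DataFrame(
            {
                "gene_A": [f"f{3 * i}" for i in range(n)],
                "gene_B": [f"f{3 * i + 1}" for i in range(n)],
                "gene_D": [f"f{3 * i + 2}" for i in range(n)],
            },
            index=pd.Index([f"t{i}" for i in range(n)], name="triad_id"),
        )
    )


class TestContributions:
    def test_total_exactly_five_is_kept(self):
        t = _rpm_table([[2.0], [2.0], [1.0]], ["A", "B", "D"])
        out = triad_contributions(t, _triad_table(1))
        assert list(out.index) == ["t0"]
        np.testing.assert_allclose(out[["A", "B", "D"]].iloc[0], [0.4, 0.4, 0.2])

    def test_total_below_five_removed(self):
        t = _rpm_table([[2.0], [2.0], [0.9]], ["A", "B", "D"])
        assert len(triad_contributions(t, _triad_table(1))) == 0

    def test_degenerate_single_homoeolog(self):
        t = _rpm_table([[0.0], [0.0], [8.0]], ["A", "B", "D"])
        out = triad_contributions(t, _triad_table(1))
        np.testing.assert_allclose(out[["A", "B", "D"]].iloc[0], [0.0, 0.0, 1.0])

    def test_replicate_mean_used(self):
        t = _rpm_table([[2.0, 6.0], [4.0, 4.0], [0.0, 4.0]], ["A", "B", "D"])
        out = triad_contributions(t, _triad_table(1))
        np.testing.assert_allclose(out[["A", "B", "D"]].iloc[0], [0.4, 0.4, 0.2])

    def test_missing_triad_gene_rejected(self):
        t = _rpm_table([[1.0], [1.0]], ["A", "B"])
        with pytest.raises(ValidationError):
            triad_contributions(t, _triad_table(1))


class TestEigenDistance:
    @pytest.mark.parametrize(
        "p,q,expect",
        [
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1 / 3, 1 / 3, 1 / 3), (1 / 3, 1 / 3, 1 / 3), 0.0),
            ((1 / 3, 1 / 3, 1 / 3), (1, 0, 0), np.sqrt(6) / 3),
            ((1, 0, 0), (0, 1, 0), np.sqrt(2)),
            ((0.40, 0.30, 0.30), (0.34, 0.33, 0.33), np.sqrt(0.06**2 + 2 * 0.03**2)),
        ],
    )
    def test_closed_forms(self, p, q, expect):
        assert eigen_distance(p, q) == pytest.approx(expect, abs=1e-12)

    @given(
        st.lists(st.floats(0.001, 1.0), min_size=9, max_size=9),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_metric_symmetry_and_triangle_inequality(self, raw):
        pts = np.array(raw).reshape(3, 3)
        pts = pts / pts.sum(axis=1, keepdims=True)
        a, b, c = pts
        assert eigen_distance(a, b) == pytest.approx(eigen_distance(b, a), abs=1e-12)
        assert eigen_distance(a, c) <= eigen_distance(a, b) + eigen_distance(b, c) + 1e-12


class TestClassification:
    @pytest.mark.parametrize(
        "point,expect",
        [
            ((0.34, 0.33, 0.33), "Balanced"),
            ((0.90, 0.05, 0.05), "Dominant A"),
            ((0.05, 0.475, 0.475), "Suppressed A"),
            ((0.05, 0.05, 0.90), "Dominant D"),
            ((0.475, 0.05, 0.475), "Suppressed B"),
        ],
    )
    def test_examples_match_brute_force(self, point, expect):
        assert brute_force_category(point) == expect
        out = classify_triads(states_df([point]))
        assert out["category"].iloc[0] == expect

    def test_agrees_with_oracle_on_random_simplex_points(self):
        rng = np.random.default_rng(0)
        pts = rng.dirichlet((1.0, 1.0, 1.0), size=2000)
        out = classify_triads(states_df(pts))
        oracle = [brute_force_category(p) for p in pts]
        assert list(out["category"]) == oracle

    def test_mostly_balanced_when_bias_is_central(self):
        rng = np.random.default_rng(1)
        pts = rng.dirichlet((25.0, 25.0, 25.0), size=2000)
        pts = pts[pts.max(axis=1) <= 0.5]
        out = classify_triads(states_df(pts))
        assert (out["category"] == "Balanced").mean() >= 0.95


class TestBiasCorrelation:
    def test_identical_samples_give_unit_correlation(self):
        pts = np.random.default_rng(2).dirichlet((3, 3, 3), size=50)
        df = states_df(pts)
        r, paired = bias_correlation(df, df)
        assert r == pytest.approx(1.0)
        assert len(paired) == 150

    def test_swapped_contributions_break_identity(self):
        rng = np.random.default_rng(3)
        pts = rng.dirichlet((8, 3, 1), size=100)
        swapped = pts[:, [2, 1, 0]]
        r, _ = bias_correlation(states_df(pts), states_df(swapped))
        assert r < 1.0

    def test_parental_legacy_recovered_from_simulation(self):
        # wide parental bias (uniform over the simplex) and low counting
        # noise, so the correlation reflects inheritance rather than noise
        cfg = SimulationConfig(n_triads=600, rng_seed=17, mismatch_rate=0.0,
                               baseline_mean=400.0, dispersion=0.02,
                               replicates={"diploid_parent": 4,
                                           "tetraploid_parent": 4, "synthetic": 4},
                               bias_spec={"alpha": (1.0, 1.0, 1.0)})
        table, triad_tbl, truth = simulate_experiment(cfg)
        roles = table.samples["role"]
        dip = table.subset_samples(table.samples.index[roles == "diploid_parent"])
        tet = table.subset_samples(table.samples.index[roles == "tetraploid_parent"])
        syn = table.subset_samples(table.samples.index[roles == "synthetic"])
        insilico = combine_parents_in_silico(
            normalize_expression(dip, "rpm"), normalize_expression(tet, "rpm")
        )
        parent_states = triad_states(insilico, triad_tbl)
        syn_states = triad_states(normalize_expression(syn, "rpm"), triad_tbl)
        r, _ = bias_correlation(parent_states, syn_states)
        assert r >= 0.95

    def test_too_few_shared_triads_rejected(self):
        df = states_df([(0.3, 0.3, 0.4)])
        with pytest.raises(ValidationError, match="shared"):
            bias_correlation(df, states_df([(0.3, 0.3, 0.4)]).set_index(pd.Index(["zz"])))


class TestMovement:
    def test_identical_states_not_reported(self):
        df = classify_triads(states_df([(0.4, 0.3, 0.3)]))
        moves = triad_movement(df, df)
        assert moves["distance"].iloc[0] == 0.0
        assert not moves["reported"].iloc[0]

    def test_vertex_to_vertex_reported(self):
        a = classify_triads(states_df([(1.0, 0.0, 0.0)]))
        b = classify_triads(states_df([(0.0, 1.0, 0.0)]))
        moves = triad_movement(a, b)
        assert moves["distance"].iloc[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert moves["reported"].iloc[0]

    def test_small_move_below_cutoff_not_reported(self):
        a = classify_triads(states_df([(0.40, 0.30, 0.30)]))
        b = classify_triads(states_df([(0.34, 0.33, 0.33)]))
        moves = triad_movement(a, b)
        assert moves["distance"].iloc[0] == pytest.approx(0.0735, abs=1e-3)
        assert not moves["reported"].iloc[0]

    def test_triads_absent_from_one_sample_excluded(self):
        a = classify_triads(states_df([(1, 0, 0), (0.3, 0.3, 0.4)]))
        b = classify_triads(states_df([(0, 1, 0)]))  # only t0 shared
        moves = triad_movement(a, b)
        assert list(moves.index) == ["t0"]

    def test_centreward_generator_moves_mostly_toward_balance(self):
        rng = np.random.default_rng(4)
        parents = rng.dirichlet((1.2, 1.2, 1.2), size=400)
        centre = np.full(3, 1 / 3)
        synth = parents + 0.8 * (centre - parents)
        a = classify_triads(states_df(parents))
        b = classify_triads(states_df(synth))
        moves = triad_movement(a, b)
        assert moves.attrs["unbalanced_to_balanced"] > moves.attrs["balanced_to_unbalanced"]


class TestBiasDeAssociation:
    def _records(self, genes, lfc, sig=None):
        sig = sig if sig is not None else [False] * len(genes)
        return pd.DataFrame(
            {"log2fc": lfc, "pvalue": 0.5, "fdr": 0.5, "significant": sig,
             "direction": ["none"] * len(genes)},
            index=pd.Index(genes, name="feature_id"),
        )

    def test_identical_distributions_give_null_t(self):
        # two dominant and two suppressed homoeologs with identical fold changes
        pts = [(0.8, 0.1, 0.1), (0.1, 0.8, 0.1), (0.05, 0.475, 0.475), (0.475, 0.05, 0.475)]
        states = classify_triads(states_df(pts))
        tt = _triad_table(4)
        genes = ["f0", "f4", "f0_s", "f4_s"]
        rec = self._records(
            ["f0", "f4", "f3", "f1"], [1.0, 1.0, 1.0, 1.0]
        )
        report = bias_de_association(states, tt, rec)
        assert report["t_statistic"] == pytest.approx(0.0)
        assert report["t_pvalue"] == pytest.approx(1.0)

    def test_proportional_contingency_table_gives_zero_chi2(self):
        from scipy import stats as sps

        chi2, p, _, _ = sps.chi2_contingency([[10, 20], [30, 60]], correction=False)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_simulated_coupling_detected(self):
        rng = np.random.default_rng(5)
        n = 250
        pts = np.vstack([
            rng.dirichlet((30, 2, 2), size=n),     # A-dominant triads
            rng.dirichlet((1, 20, 20), size=n),    # A-suppressed triads
        ])
        states = classify_triads(states_df(pts))
        tt = _triad_table(2 * n)
        genes, lfc = [], []
        for i in range(2 * n):
            genes.append(f"f{3 * i}")  # the A homoeolog
            shift = 1.0 if i < n else 0.0  # dominant homoeologs shifted up
            lfc.append(rng.normal(shift, 0.5))
        rec = self._records(genes, lfc)
        report = bias_de_association(states, tt, rec)
        assert report["n_dominant"] >= 200 and report["n_suppressed"] >= 200
        assert report["t_pvalue"] < 0.01
        assert report["t_statistic"] > 0
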