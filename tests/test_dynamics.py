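"""LOESS fitting, dynamics-range scoring, Spearman ranking and the pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hsetools as h
from hsetools.dynamics import DynamicsConfig


# ---------------------------------------------------------------------------
# independent oracles


def naive_loess(x, y, span, degree):
    """Straightforward per-point tricube local polynomial fit (np.polyfit)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = min(n, max(int(np.ceil(span * n)), degree + 1))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        hmax = d[idx].max()
        if hmax == 0:
            out[i] = y[d == 0].mean()
            continue
        w = (1 - (d[idx] / hmax) ** 3) ** 3
        coef = np.polyfit(x[idx] - x[i], y[idx], degree, w=np.sqrt(w))
        out[i] = coef[-1]
    return out


def midrank(v):
    """Average ranks with mid-rank ties, built from first principles."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_spearman(x, y):
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------------------


class TestLoess:
    def test_reproduces_quadratic_exactly(self):
        x = np.linspace(0, 1, 40)
        y = 2.0 + 3.0 * x - 4.0 * x**2
        y_hat = h.fit_loess(x, y, span=0.5, degree=2)
        np.testing.assert_allclose(y_hat, y, atol=1e-6)

    def test_constant_response_is_preserved(self):
        x = np.linspace(0, 5, 25)
        y_hat = h.fit_loess(x, np.full(25, 3.7), span=0.3, degree=2)
        np.testing.assert_allclose(y_hat, 3.7, atol=1e-9)

    def test_degree_one_reproduces_line(self):
        x = np.linspace(0, 1, 30)
        y = 1.0 - 2.0 * x
        np.testing.assert_allclose(h.fit_loess(x, y, 0.4, 1), y, atol=1e-8)

    @pytest.mark.parametrize("span,degree", [(0.3, 2), (0.5, 2), (0.3, 1), (0.8, 2)])
    def test_matches_naive_reimplementation(self, span, degree):
        rng = np.random.default_rng(17)
        x = np.sort(rng.uniform(0, 1, 80))
        y = 2 / (1 + np.exp(-(x - 0.5) / 0.1)) + rng.normal(0, 0.3, 80)
        ours = h.fit_loess(x, y, span, degree)
        theirs = naive_loess(x, y, span, degree)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_handles_tied_pseudotime(self):
        x = np.repeat(np.linspace(0, 1, 10), 3)
        rng = np.random.default_rng(0)
        y = x + rng.normal(0, 0.05, len(x))
        y_hat = h.fit_loess(x, y, 0.4, 2)
        assert y_hat.shape == x.shape and np.all(np.isfinite(y_hat))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least"):
            h.fit_loess(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="equal"):
            h.fit_loess(np.zeros(20), np.arange(20.0))


class TestDynamicsRange:
    def test_hand_computed_ratio(self):
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y_hat = np.array([0.5, 1.0, 2.0, 3.0, 3.5])
        assert h.dynamics_range(y, y_hat) == pytest.approx(0.75)

    def test_perfect_fit_scores_one(self):
        y = np.array([0.3, 2.0, 1.1, 0.9])
        assert h.dynamics_range(y, y) == pytest.approx(1.0)

    def test_flat_fit_scores_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        assert h.dynamics_range(y, np.full(3, 0.7)) == 0.0

    def test_degenerate_flat_observations(self):
        assert np.isnan(h.dynamics_range(np.ones(4), np.linspace(0, 1, 4)))

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=20)
        y_hat = naive_loess(np.linspace(0, 1, 20), y, 0.6, 1)
        base = h.dynamics_range(y, y_hat)
        assert h.dynamics_range(y + 5.0, y_hat + 5.0) == pytest.approx(base)
        assert h.dynamics_range(3.0 * y, 3.0 * y_hat) == pytest.approx(base)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            h.dynamics_range(np.arange(4.0), np.arange(5.0))


class TestClassify:
    def test_strictly_below_cutoff_is_static(self):
        scores = pd.Series({"a": 0.049, "b": 0.05, "c": 0.2, "d": np.nan})
        cls = h.classify_dynamics(scores, static_cutoff=0.05)
        assert cls.to_dict() == {
            "a": "static",
            "b": "dynamic",
            "c": "dynamic",
            "d": "degenerate",
        }

    def test_fibroblast_branch_cutoff(self):
        scores = pd.Series({"a": 0.07, "b": 0.12})
        cls = h.classify_dynamics(scores, DynamicsConfig.fibroblast_branch().static_cutoff)
        assert cls.to_dict() == {"a": "static", "b": "dynamic"}


class TestPrefilter:
    def _adata(self, detected_counts, n_cells=100):
        from anndata import AnnData

        X = np.zeros((n_cells, len(detected_counts)))
        for j, k in enumerate(detected_counts):
            X[:k, j] = 1.0
        return AnnData(
            X=X,
            obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
            var=pd.DataFrame(index=[f"g{j}" for j in range(len(detected_counts))]),
        )

    def test_ten_percent_boundary_is_inclusive(self):
        adata = self._adata([10, 9, 50])
        kept, rates = h.prefilter_genes(adata, None)
        assert kept == ["g0", "g2"]
        assert rates["g1"] == pytest.approx(0.09)

    def test_zero_minimum_keeps_all(self):
        adata = self._adata([0, 1, 99])
        kept, _ = h.prefilter_genes(adata, None, DynamicsConfig(detection_min_fraction=0.0))
        assert kept == ["g0", "g1", "g2"]


class TestSpearman:
    def test_perfect_concordance(self):
        x = np.linspace(0, 1, 12)
        assert h.spearman_rank(x, np.exp(x))[0] == pytest.approx(1.0)
        assert h.spearman_rank(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_all_tied_convention(self):
        assert h.spearman_rank(np.arange(5.0), np.ones(5)) == (0.0, 1.0)

    def test_matches_brute_force_midrank_on_grid(self):
        # exhaustive small inputs with ties from a fixed value grid
        x = np.arange(5.0)
        for y in itertools.product([0.0, 1.0, 2.0], repeat=5):
            y = np.array(y)
            if np.ptp(y) == 0:
                continue
            rho, _ = h.spearman_rank(x, y)
            assert rho == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_matches_brute_force_with_tied_pseudotime(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 3, 8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = h.spearman_rank(x, y)
            assert rho == pytest.approx(brute_spearman(x, y), abs=1e-12)


class TestRankFateGenes:
    def _records(self, rhos, ps):
        return pd.DataFrame(
            {"rho": rhos, "p_value": ps},
            index=pd.Index([f"g{i}" for i in range(len(rhos))], name="gene_id"),
        )

    def test_bonferroni_multiply_and_cap(self):
        recs = self._records([0.9] * 40, [0.001] * 40)
        out, *_ = h.rank_fate_genes(recs, DynamicsConfig())
        np.testing.assert_allclose(out["p_adjusted"], 0.04)
        recs2 = self._records([0.9, 0.8], [0.9, 0.2])
        out2, *_ = h.rank_fate_genes(recs2, DynamicsConfig())
        assert out2["p_adjusted"].max() == 1.0
        assert np.all(out2["p_adjusted"] >= out2["p_value"])

    def test_rho_cutoff_is_strict(self):
        recs = self._records([0.71, 0.70, -0.75, 0.1], [0.01] * 4)
        _, fate, _, _ = h.rank_fate_genes(recs, DynamicsConfig())
        assert set(fate.index) == {"g0", "g2"}

    def test_top_k_per_direction(self):
        rng = np.random.default_rng(6)
        rhos = np.concatenate([rng.uniform(0.1, 0.9, 25), -rng.uniform(0.1, 0.9, 5)])
        recs = self._records(rhos, np.full(30, 1e-4))
        _, _, up, down = h.rank_fate_genes(recs, DynamicsConfig(top_k=20))
        assert len(up) == 20 and len(down) == 5
        assert np.all(np.diff(up["rho"].abs()) <= 1e-12)

    def test_tie_break_by_p_then_gene_id(self):
        recs = self._records([0.5, 0.5, 0.5], [0.02, 0.01, 0.02])
        _, _, up, _ = h.rank_fate_genes(recs, DynamicsConfig(top_k=3))
        assert list(up.index) == ["g1", "g0", "g2"]


class TestPipeline:
    def test_recovers_planted_dynamics(self, study_dataset, study_result):
        """Reference conditions: the pericyte-branch presets recover the truth."""
        sel, res = study_result
        truth = study_dataset.truth
        rec = res.records
        mono = truth[truth.isin(["dynamic_up", "dynamic_down"])].index
        sens = (rec.loc[mono, "dynamics_class"] == "dynamic").mean()
        assert sens >= 0.9
        up = truth[truth == "dynamic_up"].index
        down = truth[truth == "dynamic_down"].index
        assert np.all(rec.loc[up, "rho"].dropna() > 0)
        assert np.all(rec.loc[down, "rho"].dropna() < 0)
        static = truth[truth == "static"].index
        false_pos = len(set(res.fate_genes.index) & set(static))
        assert false_pos / len(static) <= 0.05

    def test_zero_dynamic_genes_empty_fate_lists(self):
        ds = h.generate_trajectory_dataset(
            h.TrajectorySimConfig(n_cells=120, n_genes=40, frac_dynamic=0.0, seed=3)
        )
        res = h.run_dynamics_pipeline(ds.adata, None, ds.pseudotime, DynamicsConfig())
        assert len(res.fate_genes) == 0 or res.fate_genes["rho"].abs().max() <= 0.7
        # static truth everywhere: nothing should correlate strongly
        assert len(res.fate_genes) == 0

    def test_gene_order_invariance(self, small_dataset):
        ds = small_dataset
        sel = h.select_cells_near_path(ds.embedding, ds.path, 0.5)
        res1 = h.run_dynamics_pipeline(ds.adata, sel, ds.pseudotime, DynamicsConfig())
        rng = np.random.default_rng(1)
        perm = rng.permutation(ds.adata.n_vars)
        shuffled = ds.adata[:, perm].copy()
        res2 = h.run_dynamics_pipeline(shuffled, sel, ds.pseudotime, DynamicsConfig())
        a = res1.records.sort_index()
        b = res2.records.sort_index()
        pd.testing.assert_frame_equal(a, b, check_like=True)

    def test_provenance_columns_present(self, study_result):
        _, res = study_result
        for col in [
            "detection_rate",
            "passed_prefilter",
            "dynamics_range",
            "dynamics_class",
            "rho",
            "p_value",
            "p_adjusted",
            "direction",
            "rank_in_direction",
        ]:
            assert col in res.records.columns
        # rho exists exactly for dynamic-class genes
        dyn = res.records["dynamics_class"] == "dynamic"
        assert res.records.loc[dyn, "rho"].notna().all()
        assert res.records.loc[~dyn, "rho"].isna().all()

    def test_missing_pseudotime_is_reported(self, small_dataset):
        ds = small_dataset
        sel = h.select_cells_near_path(ds.embedding, ds.path, 0.5)
        with pytest.raises(ValueError, match="pseudotime"):
            h.run_dynamics_pipeline(ds.adata, sel, ds.pseudotime.iloc[:10], DynamicsConfig())
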