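"""Normalization and EV pipelines against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from evnet.datatypes import ExpressionMatrix
from evnet.errors import ValidationError
from evnet.ev import (ck_log_ratios, collapse_probes, ev_ck, ev_expo,
                      median_log2_rows, quantile_normalize, subset_ev)
from evnet.simulate import SimConfig, generate_tissue_compendium

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent straight-line oracles
# ---------------------------------------------------------------------------

def oracle_quantile_normalize(X):
    """Sort each column, average across columns per rank, map back by
    within-column rank; ties get the mean of their target values."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    ref = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        for val in np.unique(X[:, j]):
            mask = X[:, j] == val
            assigned[mask] = assigned[mask].mean()
        out[:, j] = assigned
    return out


def oracle_ev_expo(X):
    """Direct recomputation of the tissue-compendium EV formulas."""
    qn = oracle_quantile_normalize(X)
    evs, means = [], []
    for row, qrow in zip(np.asarray(X, float), qn):
        med = np.median(qrow)
        logr = np.log2(qrow / med)
        evs.append(np.sum((logr - logr.mean()) ** 2) / (len(logr) - 1))
        means.append(qrow.mean())
    return np.array(evs), np.array(means)


def oracle_ev_ck(X, control_of):
    """Direct recomputation of the control-relative EV formulas."""
    X = np.asarray(X, float)
    cols = []
    for j, ctrl in control_of.items():
        lr = np.log2(X[:, j] / X[:, ctrl])
        mu, sd = lr.mean(), lr.std(ddof=1)
        cols.append((lr - mu) / sd)
    Z = np.column_stack(cols)
    return Z.var(axis=1, ddof=1)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_worked_example(self):
        m = make_matrix([[5, 4], [2, 8], [3, 6]])
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, [[6.5, 3], [3, 6.5], [4.5, 4.5]])

    def test_identical_columns_fixed_point(self):
        m = make_matrix(np.tile([[3.0], [1.0], [7.0]], (1, 4)))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.lognormal(size=(15, 6)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), rtol=1e-14)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(size=(40, 5))
        out = quantile_normalize(make_matrix(X)).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=1e-14)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(3, 21)
            p = rng.integers(2, 9)
            X = rng.integers(1, 6, size=(n, p)).astype(float)  # heavy ties
            got = quantile_normalize(make_matrix(X)).values.to_numpy()
            np.testing.assert_allclose(got, oracle_quantile_normalize(X),
                                       rtol=1e-12)

    def test_single_column_returned_unchanged(self):
        m = make_matrix([[1.0], [2.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_rejects_missing_values(self):
        frame = pd.DataFrame([[1.0, np.nan]], index=["g0"], columns=["a", "b"])
        m = ExpressionMatrix.__new__(ExpressionMatrix)
        m.values, m.samples, m.scale, m.probe_to_gene = (
            frame, pd.DataFrame(index=["a", "b"]), "intensity", None)
        with pytest.raises(ValidationError):
            quantile_normalize(m)


# ---------------------------------------------------------------------------
# median/log2 row normalization
# ---------------------------------------------------------------------------

class TestMedianLog2Rows:
    def test_worked_example(self):
        out = median_log2_rows(make_matrix([[2, 2, 8, 8]]))
        np.testing.assert_allclose(
            out.values.to_numpy()[0],
            [-1.3219281, -1.3219281, 0.6780719, 0.6780719], atol=1e-6)

    def test_constant_row_maps_to_zero(self):
        out = median_log2_rows(make_matrix([[7, 7, 7]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[0, 0, 0]])

    def test_zero_row_dropped_with_report(self):
        m = make_matrix([[0, 0, 0], [1, 2, 4]])
        out, dropped = median_log2_rows(m, return_dropped=True)
        assert list(out.values.index) == ["g1"]
        assert dropped[0][0] == "g0"
        assert "median" in dropped[0][1]

    def test_scale_flag_flips(self):
        out = median_log2_rows(make_matrix([[1, 2, 4]]))
        assert out.scale == "log_ratio"


# ---------------------------------------------------------------------------
# tissue-compendium EV
# ---------------------------------------------------------------------------

class TestEvExpo:
    def test_constant_gene_zero_ev(self):
        ev = ev_expo(make_matrix(np.tile([[5.0], [5.0]], (1, 6))))
        assert (ev["ev"] == 0).all()

    def test_worked_example_row(self):
        # every column holds the multiset {2, 8}, so quantile normalization
        # is the identity; each row then has median 5, log-ratios with +-1
        # deviations, and sample variance 4 * 1 / 3
        ev = ev_expo(make_matrix([[2, 2, 8, 8], [8, 8, 2, 2]]))
        np.testing.assert_allclose(ev["ev"].to_numpy(), 4.0 / 3.0, rtol=1e-12)

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = rng.integers(2, 21)
            p = rng.integers(2, 9)
            X = rng.lognormal(mean=2.0, sigma=1.0, size=(n, p))
            got = ev_expo(make_matrix(X))
            want_ev, want_mean = oracle_ev_expo(X)
            np.testing.assert_allclose(got["ev"].to_numpy(), want_ev, rtol=1e-12)
            np.testing.assert_allclose(got["mean_expr"].to_numpy(), want_mean,
                                       rtol=1e-12)

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(4)
        X = rng.lognormal(size=(12, 6))
        m = make_matrix(X)
        ev1 = ev_expo(m)
        shuffled = m.values.sample(frac=1, axis=0, random_state=0).sample(
            frac=1, axis=1, random_state=1)
        ev2 = ev_expo(ExpressionMatrix(shuffled, None, "intensity"))
        pd.testing.assert_series_equal(ev1["ev"].sort_index(),
                                       ev2["ev"].sort_index())

    def test_row_scaling_invariance(self):
        # quantile normalization mixes rows, so test the median-ratio step
        # directly: scaling an intensity row leaves its log-ratio variance
        # unchanged
        row = np.array([[1.0, 2.0, 5.0, 9.0]])
        v1 = median_log2_rows(make_matrix(row)).values.to_numpy().var(ddof=1)
        v2 = median_log2_rows(make_matrix(7.3 * row)).values.to_numpy().var(ddof=1)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_separates_planted_variance_classes(self, small_config):
        matrix, truth = generate_tissue_compendium(small_config)
        ev = ev_expo(matrix)
        high = ev.loc[[g for g, c in truth.variance_class.items() if c == "high"], "ev"]
        low = ev.loc[[g for g, c in truth.variance_class.items() if c == "low"], "ev"]
        # separation AUC: fraction of (high, low) pairs correctly ordered
        auc = (high.to_numpy()[:, None] > low.to_numpy()[None, :]).mean()
        assert auc >= 0.95


# ---------------------------------------------------------------------------
# treatment-compendium EV
# ---------------------------------------------------------------------------

def _paired_matrix(X, pairs):
    """Matrix with metadata pairing treatment columns to controls."""
    X = np.asarray(X, float)
    cols = [f"s{j}" for j in range(X.shape[1])]
    meta = pd.DataFrame({
        "tissue": "",
        "treatment": ["t" if j in pairs else "control" for j in range(X.shape[1])],
        "control_id": [f"s{pairs[j]}" if j in pairs else "" for j in range(X.shape[1])],
    }, index=cols)
    frame = pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])], columns=cols)
    return ExpressionMatrix(frame, meta, "intensity")


class TestEvCk:
    def test_single_pair_prestandardized_values(self):
        ctrl = np.full(10, 50.0)
        treat = ctrl.copy()
        treat[0] *= 2.0  # gene A doubles, everything else unchanged
        m = _paired_matrix(np.column_stack([ctrl, treat]), {1: 0})
        logfc = ck_log_ratios(m)
        np.testing.assert_allclose(logfc.iloc[0, 0], 1.0)
        np.testing.assert_allclose(logfc.iloc[1:, 0], 0.0)

    def test_column_identical_to_control_dropped(self):
        ctrl = np.array([1.0, 2.0, 4.0])
        X = np.column_stack([ctrl, ctrl, ctrl * [1, 2, 4]])
        m = _paired_matrix(X, {1: 0, 2: 0})
        logfc, dropped = ck_log_ratios(m, return_dropped=True)
        assert [d[0] for d in dropped] == ["s1"]
        assert list(logfc.columns) == ["s2"]

    def test_missing_control_is_error(self):
        X = np.ones((3, 2))
        cols = ["s0", "s1"]
        meta = pd.DataFrame({"tissue": "", "treatment": ["control", "t"],
                             "control_id": ["", "nope"]}, index=cols)
        m = ExpressionMatrix(pd.DataFrame(X, index=list("abc"), columns=cols),
                             meta, "intensity")
        with pytest.raises(ValidationError):
            ev_ck(m)

    def test_matches_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = rng.integers(4, 21)
            n_pairs = rng.integers(2, 5)
            ctrl = rng.lognormal(size=(n, n_pairs))
            treat = ctrl * rng.lognormal(sigma=0.7, size=(n, n_pairs))
            X = np.empty((n, 2 * n_pairs))
            X[:, ::2] = ctrl
            X[:, 1::2] = treat
            pairs = {2 * j + 1: 2 * j for j in range(n_pairs)}
            got = ev_ck(_paired_matrix(X, pairs))["ev"].to_numpy()
            want = oracle_ev_ck(X, pairs)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_standardized_columns_have_unit_variance(self):
        rng = np.random.default_rng(6)
        ctrl = rng.lognormal(size=(20, 3))
        treat = ctrl * rng.lognormal(sigma=0.5, size=(20, 3))
        X = np.column_stack([ctrl[:, 0], treat[:, 0], ctrl[:, 1], treat[:, 1],
                             ctrl[:, 2], treat[:, 2]])
        pairs = {1: 0, 3: 2, 5: 4}
        logfc = ck_log_ratios(_paired_matrix(X, pairs))
        std = (logfc - logfc.mean()) / logfc.std(ddof=1)
        np.testing.assert_allclose(std.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.var(ddof=1), 1.0, rtol=1e-12)


# ---------------------------------------------------------------------------
# probe collapsing and subsets
# ---------------------------------------------------------------------------

class TestCollapseProbes:
    def _table(self, evs):
        return pd.DataFrame({
            "ev": evs, "mean_expr": 1.0, "n_samples_used": 5,
            "dataset_tag": "expo_style",
        }, index=[f"p{i}" for i in range(len(evs))])

    def test_single_probe_identity(self):
        tab = self._table([0.4])
        out, _ = collapse_probes(tab, {"p0": "gene"})
        assert out.loc["gene", "ev"] == 0.4

    def test_median_of_three_probes(self):
        tab = self._table([0.1, 0.3, 0.9])
        out, _ = collapse_probes(tab, {f"p{i}": "gene" for i in range(3)})
        assert out.loc["gene", "ev"] == 0.3

    def test_unmapped_probe_is_error(self):
        with pytest.raises(ValidationError, match="p0"):
            collapse_probes(self._table([0.1]), {})

    def test_probe_pair_qc_positive_on_shared_signal(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, probes_per_gene_range=(2, 2))
        matrix, _ = generate_tissue_compendium(cfg)
        probe_ev = ev_expo(matrix)
        _, qc = collapse_probes(probe_ev, matrix.probe_to_gene, seed=0)
        assert qc > 0


class TestSubsetEv:
    def test_identity_filter_matches_full(self, small_config):
        matrix, _ = generate_tissue_compendium(small_config)
        full = ev_expo(matrix)
        sub = subset_ev(matrix, lambda row: True)
        pd.testing.assert_frame_equal(full, sub)

    def test_disjoint_tissue_subsets_correlate(self, small_config):
        from evnet.stats import spearman

        matrix, _ = generate_tissue_compendium(small_config)
        ev_a = subset_ev(matrix, lambda row: row["tissue"] in ("T00", "T01"))
        ev_b = subset_ev(matrix, lambda row: row["tissue"] in ("T02", "T03"))
        rho = spearman(ev_a["ev"], ev_b["ev"])
        assert rho.estimate >= 0.4

    def test_empty_filter_is_error(self, small_config):
        matrix, _ = generate_tissue_compendium(small_config)
        with pytest.raises(ValidationError, match="0 samples"):
            subset_ev(matrix, lambda row: False)
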