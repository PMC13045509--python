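import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

from coroquant import (
    bland_altman,
    cohen_kappa,
    confusion_from_labels,
    icc,
    mae,
    overlap_metrics,
    wilson_interval,
)


def _icc_oracle(x):
    """Independent transcription of the two-way random-effects ANOVA
    decomposition for ICC(2,1), written as explicit loops."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i]) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum(
        (x[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = (rng.random((20, 20)) < 0.4).astype(int)
        out = overlap_metrics(m, m)
        assert out["dsc"] == 1.0 and out["sensitivity"] == 1.0
        assert out["specificity"] == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, :] = 1
        b[1, :] = 1
        assert overlap_metrics(a, b)["dsc"] == 0.0

    def test_half_coverage(self):
        truth = np.zeros((4, 4), dtype=int)
        truth[:2, :] = 1
        pred = np.zeros((4, 4), dtype=int)
        pred[0, :] = 1  # half of truth, no FP
        assert overlap_metrics(pred, truth)["dsc"] == pytest.approx(2 / 3)

    def test_undefined_reported_as_none(self):
        z = np.zeros((3, 3), dtype=int)
        out = overlap_metrics(z, z)
        assert out["dsc"] is None and out["sensitivity"] is None
        assert out["specificity"] == 1.0

    def test_dsc_ppv_sensitivity_identity(self, rng):
        """DSC = harmonic mean of PPV and sensitivity on random mask pairs."""
        checked = 0
        for _ in range(100):
            a = (rng.random((12, 12)) < 0.4).astype(int)
            b = (rng.random((12, 12)) < 0.4).astype(int)
            out = overlap_metrics(a, b)
            if None in (out["dsc"], out["ppv"], out["sensitivity"]):
                continue
            if out["ppv"] + out["sensitivity"] == 0:
                continue
            expected = (
                2 * out["ppv"] * out["sensitivity"] / (out["ppv"] + out["sensitivity"])
            )
            assert out["dsc"] == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked >= 90

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(np.zeros((2, 2)), np.zeros((3, 3)))


class TestConfusion:
    def test_perfect_prediction(self):
        truth = [True, False, True, False]
        counts, metrics = confusion_from_labels(truth, truth)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (2, 2, 0, 0)
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert metrics[name]["value"] == 1.0

    def test_all_negative_prediction(self):
        pred = [False] * 6
        truth = [True, True, False, False, False, True]
        _, metrics = confusion_from_labels(pred, truth)
        assert metrics["sensitivity"]["value"] == 0.0
        assert metrics["specificity"]["value"] == 1.0
        assert metrics["ppv"] is None  # no positive calls

    def test_wilson_ci_matches_statsmodels(self):
        for k, n in [(5, 10), (0, 7), (7, 7), (19, 400), (1, 3)]:
            lo, hi = wilson_interval(k, n)
            sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(sm_lo, abs=1e-12)
            assert hi == pytest.approx(sm_hi, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_labels([], [])


class TestMAE:
    def test_identical_zero(self):
        assert mae([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_symmetric_unit_errors(self):
        assert mae([1.0, -1.0], [0.0, 0.0]) == 1.0

    def test_matches_loop_oracle(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        loop = sum(abs(x - y) for x, y in zip(a, b)) / 50
        assert mae(a, b) == pytest.approx(loop, abs=1e-12)


class TestBlandAltman:
    def test_identical_vectors(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_closed_form_pair(self):
        bias, lo, hi = bland_altman([1.0, -1.0], [0.0, 0.0])
        sd = math.sqrt(2)
        assert bias == 0.0
        assert lo == pytest.approx(-1.96 * sd)
        assert hi == pytest.approx(1.96 * sd)

    def test_matches_independent_formula(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        d = a - b
        bias, lo, hi = bland_altman(a, b)
        sd = math.sqrt(sum((x - d.mean()) ** 2 for x in d) / 39)
        assert bias == pytest.approx(d.mean(), abs=1e-12)
        assert hi - bias == pytest.approx(1.96 * sd, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(8.0)[:, None], (1, 3))
        value, lo, hi = icc(x)
        assert value == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(500, 3))  # no subject effect
        value, lo, hi = icc(x)
        assert abs(value) < 0.08
        assert lo < value < hi

    def test_matches_anova_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=(6, 4)) + rng.normal(size=(6, 1))
            assert icc(x)[0] == pytest.approx(_icc_oracle(x), abs=1e-12)

    def test_matches_pingouin(self, rng):
        x = rng.normal(size=(10, 4)) + 2 * rng.normal(size=(10, 1))
        n, k = x.shape
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(df, "subject", "rater", "score")
        row = ref[ref["Type"] == "ICC2"].iloc[0] if "ICC2" in set(ref["Type"]) \
            else ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        value, lo, hi = icc(x)
        assert value == pytest.approx(float(row["ICC"]), abs=1e-10)
        ref_lo, ref_hi = row["CI95"] if "CI95" in ref.columns else row["CI95%"]
        assert lo == pytest.approx(ref_lo, abs=5e-3)  # pingouin rounds its CI
        assert hi == pytest.approx(ref_hi, abs=5e-3)

    def test_degenerate_variance_undefined(self):
        assert icc(np.full((5, 3), 2.0)) == (None, None, None)


class TestKappa:
    def test_perfect_agreement(self):
        a = [True, False, True, False, True]
        assert cohen_kappa(a, a) == pytest.approx(1.0)

    def test_chance_agreement_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.random(20000) < 0.3
        b = rng.random(20000) < 0.3  # independent raters
        assert abs(cohen_kappa(a, b)) < 0.03

    def test_hand_formula_2x2_table(self):
        # table: both+ 45, a+/b- 15, a-/b+ 25, both- 15
        a = [True] * 60 + [False] * 40
        b = [True] * 45 + [False] * 15 + [True] * 25 + [False] * 15
        po = (45 + 15) / 100
        pe = 0.60 * 0.70 + 0.40 * 0.30
        expected = (po - pe) / (1 - pe)
        assert cohen_kappa(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(5):
            a = rng.random(60) < 0.4
            b = a ^ (rng.random(60) < 0.2)
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_degenerate_marginals_undefined(self):
        assert cohen_kappa([True, True], [True, True]) is None


class TestPermutationInvariance:
    def test_paired_permutation_leaves_metrics_unchanged(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        perm = rng.permutation(30)
        assert mae(a, b) == pytest.approx(mae(a[perm], b[perm]), abs=1e-12)
        assert bland_altman(a, b)[0] == pytest.approx(
            bland_altman(a[perm], b[perm])[0], abs=1e-12
        )
        pred = rng.random(30) < 0.5
        truth = rng.random(30) < 0.5
        c1, _ = confusion_from_labels(pred, truth)
        c2, _ = confusion_from_labels(pred[perm], truth[perm])
        assert (c1.tp, c1.fp, c1.tn, c1.fn) == (c2.tp, c2.fp, c2.tn, c2.fn)
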