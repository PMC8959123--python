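"""Evaluation statistics: MDE, Cronbach's alpha, kappa variants, and
confusion-matrix metrics, each checked against an independent route."""

import numpy as np
import pandas as pd
import pytest

from hipmorph.detection import OracleProvider
from hipmorph.evalstats import (
    ConfusionMatrix,
    RaterMatrix,
    StatisticUndefined,
    alpha_satisfactory,
    binary_metrics,
    cohen_kappa,
    cronbach_alpha,
    icc2_1,
    interpret_kappa,
    mean_distance_error,
    weighted_linear_kappa,
)
from hipmorph.synthetic import PelvisParams, generate_case


def brute_force_weighted_kappa(counts: np.ndarray) -> float:
    """Independent double-sum implementation of linear weighted kappa."""
    c = np.asarray(counts, dtype=float)
    k = c.shape[0]
    n = c.sum()
    row = c.sum(axis=1) / n
    col = c.sum(axis=0) / n
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - abs(i - j) / (k - 1)
            po += w * c[i, j] / n
            pe += w * row[i] * col[j]
    return (po - pe) / (1.0 - pe)


class TestMeanDistanceError:
    def test_identity_gives_zeros(self, default_case):
        mde, misses = mean_distance_error([default_case.truth], [default_case.truth])
        assert (mde.to_numpy() == 0).all()
        assert (misses.to_numpy() == 0).all()

    def test_uniform_shift_is_345(self, default_case):
        from dataclasses import replace

        from hipmorph.geometry import Point2D

        lms = default_case.truth

        def shift_hip(h):
            pts = {
                n: None
                if getattr(h, n) is None
                else Point2D(getattr(h, n).x + 3, getattr(h, n).y + 4)
                for n in ("E", "Y", "C", "H")
            }
            return replace(h, **pts)

        moved = replace(lms, left=shift_hip(lms.left), right=shift_hip(lms.right))
        mde, _ = mean_distance_error([lms], [moved])
        assert mde.to_numpy() == pytest.approx(np.full((4, 2), 5.0))

    def test_missing_prediction_counts_as_miss(self, default_case):
        from dataclasses import replace

        lms = default_case.truth
        pred = replace(lms, left=replace(lms.left, C=None))
        mde, misses = mean_distance_error([lms], [pred])
        assert misses.loc["C", "left"] == 1
        assert np.isnan(mde.loc["C", "left"])
        assert mde.loc["C", "right"] == 0.0

    def test_jittered_cohort_matches_rayleigh_mean(self):
        """Isotropic Gaussian jitter of sigma per axis has mean radial
        error sigma*sqrt(pi/2); the sampled MDE must sit within 3 SE."""
        sigma, n = 3.7, 300
        case = generate_case(PelvisParams())
        truth, pred = [], []
        for i in range(n):
            bundle = OracleProvider(case, sigma_px=sigma, seed=1000 + i).provide()
            truth.append(case.truth)
            pred.append(bundle.landmarks)
        mde, _ = mean_distance_error(truth, pred)
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(n)
        assert np.abs(mde.to_numpy() - expected).max() < 3 * se

    def test_mismatched_lengths_rejected(self, default_case):
        with pytest.raises(ValueError):
            mean_distance_error([default_case.truth], [])


class TestCronbachAlpha:
    def test_duplicated_rater_gives_exactly_one(self, rng):
        x = rng.normal(20, 5, size=50)
        assert cronbach_alpha(RaterMatrix(np.column_stack([x, x]))) == 1.0

    def test_independent_noise_alpha_near_zero(self):
        rng = np.random.default_rng(2024)
        m = rng.normal(size=(10_000, 2))
        assert abs(cronbach_alpha(RaterMatrix(m))) < 0.1

    def test_matches_pingouin(self, rng):
        m = rng.normal(size=(60, 4)) + rng.normal(size=(60, 1))
        import pingouin as pg

        ours = cronbach_alpha(RaterMatrix(m))
        theirs = pg.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_satisfactory_threshold(self):
        assert alpha_satisfactory(0.75)
        assert alpha_satisfactory(1.0)
        assert not alpha_satisfactory(0.7499)

    def test_shift_and_scale_invariance(self, rng):
        m = rng.normal(size=(40, 3)) + rng.normal(size=(40, 1))
        a0 = cronbach_alpha(RaterMatrix(m))
        assert cronbach_alpha(RaterMatrix(m + 7.5)) == pytest.approx(a0, abs=1e-12)
        assert cronbach_alpha(RaterMatrix(m * 3.25)) == pytest.approx(a0, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(StatisticUndefined):
            cronbach_alpha(RaterMatrix(np.ones((5, 3))))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            RaterMatrix(np.ones((1, 3)))


def test_icc2_1_matches_pingouin(rng):
    m = rng.normal(size=(30, 3)) + 2 * rng.normal(size=(30, 1))
    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(30), 3),
            "rater": np.tile(np.arange(3), 30),
            "score": m.ravel(),
        }
    )
    icc = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    )
    # ICC(2,1) is ICC(A,1) in McGraw–Wong naming
    theirs = icc.loc[icc["Type"] == "ICC(A,1)", "ICC"].item()
    assert icc2_1(RaterMatrix(m)) == pytest.approx(theirs, abs=1e-8)


class TestKappa:
    def test_diagonal_matrix_is_one(self):
        cm = ConfusionMatrix(np.diag([5, 8, 3, 4]))
        assert cohen_kappa(cm) == pytest.approx(1.0)
        assert weighted_linear_kappa(cm) == pytest.approx(1.0)

    def test_hand_evaluated_2x2(self):
        # p_o = 35/50 = 0.7; p_e = (25*30 + 25*20)/2500 = 0.5; kappa = 0.4
        cm = ConfusionMatrix([[20, 5], [10, 15]])
        assert cohen_kappa(cm) == pytest.approx(0.4, abs=1e-12)

    def test_weighted_equals_unweighted_for_k2(self, rng):
        for _ in range(10):
            cm = ConfusionMatrix(rng.integers(1, 30, size=(2, 2)))
            assert weighted_linear_kappa(cm) == pytest.approx(
                cohen_kappa(cm), abs=1e-12
            )

    def test_weighted_matches_brute_force_double_sum(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 40, size=(4, 4)) + np.eye(4, dtype=int)
            cm = ConfusionMatrix(counts)
            assert weighted_linear_kappa(cm) == pytest.approx(
                brute_force_weighted_kappa(counts), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        labels = [1, 2, 3, 4]
        a = rng.integers(1, 5, size=500)
        b = np.where(rng.random(500) < 0.6, a, rng.integers(1, 5, size=500))
        cm = ConfusionMatrix.from_labels(a, b, labels)
        assert cohen_kappa(cm) == pytest.approx(cohen_kappa_score(a, b), abs=1e-10)
        assert weighted_linear_kappa(cm) == pytest.approx(
            cohen_kappa_score(a, b, weights="linear"), abs=1e-10
        )

    def test_independent_raters_kappa_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 4, size=20_000)
        b = rng.integers(0, 4, size=20_000)
        cm = ConfusionMatrix.from_labels(a, b, [0, 1, 2, 3])
        # SE of kappa under independence ~ 1/sqrt(n·(1−p_e)) ≈ 0.01
        assert abs(cohen_kappa(cm)) < 0.03

    def test_degenerate_single_category_undefined(self):
        with pytest.raises(StatisticUndefined):
            cohen_kappa(ConfusionMatrix([[10, 0], [0, 0]]))

    def test_kappa_bounds(self, rng):
        for _ in range(50):
            cm = ConfusionMatrix(rng.integers(0, 20, size=(3, 3)) + 1)
            assert -1.0 <= cohen_kappa(cm) <= 1.0
            assert -1.0 <= weighted_linear_kappa(cm) <= 1.0


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.40, "poor_to_slight"),
            (0.405, "moderate"),
            (0.75, "moderate"),
            (0.76, "perfect"),
            (-0.2, "poor_to_slight"),
            (1.0, "perfect"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_kappa(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestBinaryMetrics:
    def test_direct_arithmetic(self):
        cm = ConfusionMatrix([[9, 1], [2, 8]])
        m = binary_metrics(cm)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)

    def test_perfect_case(self):
        m = binary_metrics(ConfusionMatrix([[10, 0], [0, 10]]))
        assert all(v == 1.0 for k, v in m.items() if k != "missed_diagnosis_rate")
        assert m["missed_diagnosis_rate"] == 0.0

    def test_missed_rate_complements_sensitivity(self, rng):
        for _ in range(20):
            cm = ConfusionMatrix(rng.integers(1, 50, size=(2, 2)))
            m = binary_metrics(cm)
            assert m["missed_diagnosis_rate"] + m["sensitivity"] == pytest.approx(1.0)

    def test_empty_margin_undefined(self):
        with pytest.raises(StatisticUndefined):
            binary_metrics(ConfusionMatrix([[0, 0], [3, 7]]))
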