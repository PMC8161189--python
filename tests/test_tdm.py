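"""Deviation statistics for predicted-vs-observed trough levels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclopbpk.tdm import (
    MatchedPair,
    TroughAgreement,
    absolute_deviation,
    bias,
    fold_agreement,
    mpe,
    mrd,
    precision,
    residuum,
    stratify,
    summarize,
)


def pair(pred, obs, pid="p1", dose=100.0, bw_dose=1.0):
    return MatchedPair(patient_id=pid, dose_mg=dose, bw_dose_mg_kg=bw_dose,
                       c0_pred=pred, c0_obs=obs)


OUTLIER = pair(93.0, 5.0)  # the cohort's most extreme matched pair

positive_conc = st.floats(min_value=0.5, max_value=5000.0,
                          allow_nan=False, allow_infinity=False)
pair_lists = st.lists(st.tuples(positive_conc, positive_conc), min_size=1, max_size=50)


class TestElementaryStatistics:
    def test_signed_deviation(self):
        assert absolute_deviation(OUTLIER) == 88.0
        assert absolute_deviation(pair(100.0, 479.0)) == -379.0
        assert absolute_deviation(pair(42.0, 42.0)) == 0.0

    def test_residuum_of_outlier(self):
        assert round(residuum(93.0, 5.0), 2) == 1.27

    def test_residuum_twofold(self):
        assert residuum(200.0, 100.0) == pytest.approx(0.3010, abs=5e-5)
        assert residuum(50.0, 50.0) == 0.0

    def test_residuum_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            residuum(0.0, 10.0)

    def test_bias(self):
        assert bias([pair(110, 100), pair(90, 100)]) == 0.0
        assert bias([OUTLIER]) == -88.0
        assert bias([pair(7, 7), pair(3, 3)]) == 0.0

    def test_precision(self):
        assert precision([pair(110, 100), pair(90, 100)]) == pytest.approx(10.0)
        assert precision([OUTLIER]) == pytest.approx(88.0)
        assert precision([pair(5, 5)]) == 0.0

    def test_mrd(self):
        assert mrd([pair(10, 10)]) == pytest.approx(1.0)
        assert mrd([pair(200, 100)]) == pytest.approx(2.0, rel=1e-6)
        assert mrd([OUTLIER]) == pytest.approx(18.6, abs=0.05)

    def test_mpe(self):
        assert mpe([pair(10, 10)]) == 0.0
        assert mpe([OUTLIER]) == pytest.approx(1760.0)
        assert mpe([pair(110, 100), pair(90, 100)]) == 0.0

    def test_fold_agreement(self):
        assert fold_agreement([pair(10, 10)], 2.0) == 1.0
        assert fold_agreement([OUTLIER], 3.0) == 0.0
        with pytest.raises(ValueError):
            fold_agreement([OUTLIER], 1.0)


class TestBands:
    def test_printed_band_constants(self):
        assert round(np.log10(2.0), 2) == 0.30
        assert round(np.log10(3.0), 2) == 0.48

    def test_band_membership_equals_ratio_comparison(self):
        """|R| < log10(k) iff 1/k < pred/obs < k, over an exhaustive ratio sweep."""
        ratios = np.geomspace(0.05, 20.0, 4001)
        for k in (2.0, 3.0):
            in_band = np.abs(np.log10(ratios)) < np.log10(k)
            by_ratio = (ratios > 1.0 / k) & (ratios < k)
            assert (in_band == by_ratio).all()

    @given(pair_lists)
    @settings(max_examples=50, deadline=None)
    def test_fold_partition_exhaustive(self, raw):
        pairs = [pair(p, o) for p, o in raw]
        f2 = fold_agreement(pairs, 2.0)
        f3 = fold_agreement(pairs, 3.0)
        between = f3 - f2
        beyond = 1.0 - f3
        assert f3 >= f2
        assert between >= 0 and beyond >= -1e-12
        assert f2 + between + beyond == pytest.approx(1.0)


class TestAggregateProperties:
    @given(pair_lists)
    @settings(max_examples=50, deadline=None)
    def test_precision_decomposes_into_bias_and_variance(self, raw):
        pairs = [pair(p, o) for p, o in raw]
        dev = np.array([o - p for p, o in raw])
        assert precision(pairs) ** 2 == pytest.approx(
            bias(pairs) ** 2 + dev.var(), rel=1e-9, abs=1e-9)

    @given(pair_lists)
    @settings(max_examples=50, deadline=None)
    def test_mrd_bounds_geometric_mean_deviation(self, raw):
        pairs = [pair(p, o) for p, o in raw]
        logs = np.array([np.log10(o / p) for p, o in raw])
        assert mrd(pairs) >= 10 ** abs(logs.mean()) - 1e-9

    def test_statistics_permutation_invariant(self):
        rng = np.random.default_rng(5)
        pairs = [pair(p, o) for p, o in rng.uniform(20, 400, size=(30, 2))]
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        a, b = summarize(pairs), summarize(shuffled)
        for field in ("bias_ng_ml", "precision_ng_ml", "mrd", "mpe_percent",
                      "median_abs_dev_ng_ml", "frac_within_2fold", "frac_within_3fold", "n"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)

    def test_degenerate_cohort(self):
        pairs = [pair(c, c) for c in (50.0, 120.0, 333.0)]
        s = summarize(pairs)
        assert (s.bias_ng_ml, s.precision_ng_ml, s.mrd, s.mpe_percent) == (0, 0, 1, 0)
        assert s.frac_within_2fold == s.frac_within_3fold == 1.0

    def test_summarize_outlier_median(self):
        s = summarize([OUTLIER])
        assert s.median_abs_dev_ng_ml == 88.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestStratification:
    def test_single_patient_single_dose(self):
        pairs = [pair(100, 90), pair(100, 110)]
        g = stratify(pairs, by="patient_id")
        assert len(g) == 1 and g.loc[0, "n"] == 2

    def test_medians_monotone_when_residuum_grows_with_dose(self):
        pairs = [pair(100 * 2 ** (bw), 100.0, pid=f"p{i}", bw_dose=bw)
                 for i, bw in enumerate(np.linspace(0.1, 2.9, 12))]
        g = stratify(pairs, by="bw_dose_bin")
        med = g["median_residuum"].to_numpy()
        assert (np.diff(med) > 0).all()

    def test_patient_groups_bounded_by_cohort_size(self):
        rng = np.random.default_rng(1)
        pairs = [pair(rng.uniform(50, 200), rng.uniform(50, 200),
                      pid=f"p{rng.integers(32)}") for _ in range(200)]
        g = stratify(pairs, by="patient_id")
        assert len(g) <= 32

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValueError):
            stratify([OUTLIER], by="nonsense")


class TestAgreementModel:
    def test_from_frames_matches_and_drops(self):
        pred = pd.DataFrame({"patient_id": ["1", "2"], "dose_mg": [100.0, 100.0],
                             "c0_pred": [120.0, 80.0]})
        obs = pd.DataFrame({"patient_id": ["1", "1", "3"], "dose_mg": [100.0, 100.0, 50.0],
                            "c0_obs": [100.0, 140.0, 60.0]})
        pts = pd.DataFrame({"patient_id": ["1", "2", "3"], "body_weight_kg": [80.0, 60, 70]})
        model = TroughAgreement.from_frames(pred, obs, pts)
        assert len(model.pairs) == 2
        assert model.n_dropped == 1
        res = model.fit()
        assert res.stats.n == 2
        assert "bias" in res.summary()
        assert res.frame["bw_dose_mg_kg"].iloc[0] == pytest.approx(100.0 / 80.0)
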