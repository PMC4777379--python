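"""Feature formulas against frozen values and naive direct-summation oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import physioaffect as pa
from physioaffect.exceptions import AlignmentError, CompletenessError, InsufficientDataError
from physioaffect.preprocessing import NNSeries, Segment

# ---------------------------------------------------------------------------
# naive oracles: straight-line reimplementations with explicit loops


def oracle_hrv(nn_ms):
    n = len(nn_ms)
    mean_rr = sum(nn_ms) / n
    std_rr = math.sqrt(sum((v - mean_rr) ** 2 for v in nn_ms) / (n - 1))
    hr = [60000.0 / v for v in nn_ms]
    mean_hr = sum(hr) / n
    std_hr = math.sqrt(sum((v - mean_hr) ** 2 for v in hr) / (n - 1))
    rmssd = math.sqrt(sum((nn_ms[j + 1] - nn_ms[j]) ** 2 for j in range(n - 1)) / (n - 1))
    return {"mean_RR": mean_rr, "std_RR": std_rr, "mean_HR": mean_hr, "std_HR": std_hr, "RMSSD": rmssd}


def oracle_scl(x, fs, threshold=0.05):
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    z = [(v - mean) / std if std > 0 else 0.0 for v in x]
    fd_raw = sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1)
    fd_norm = sum(abs(z[i + 1] - z[i]) for i in range(n - 1)) / (n - 1)
    sd_raw = sum(abs(x[i + 2] - x[i]) for i in range(n - 2)) / (n - 2)
    sd_norm = sum(abs(z[i + 2] - z[i]) for i in range(n - 2)) / (n - 2)

    # walk the turning points; amplitude relative to previous opposite extremum
    max_amps, min_amps = [], []
    anchor = x[0]
    prev_sign = 0
    for i in range(n - 1):
        d = x[i + 1] - x[i]
        if d == 0:
            continue
        s = 1 if d > 0 else -1
        if prev_sign == 0:
            prev_sign = s
        elif s != prev_sign:
            if prev_sign > 0:
                max_amps.append(x[i] - anchor)
            else:
                min_amps.append(anchor - x[i])
            anchor = x[i]
            prev_sign = s
    kept_max = [a for a in max_amps if a > threshold]
    kept_min = [a for a in min_amps if a > threshold]

    integral = sum((x[i] + x[i + 1]) / 2.0 * (1.0 / fs) for i in range(n - 1))
    t = [i / fs for i in range(n)]
    tbar = sum(t) / n
    slope = sum((t[i] - tbar) * (x[i] - mean) for i in range(n)) / sum((ti - tbar) ** 2 for ti in t)
    return {
        "SCL_mean": mean,
        "SCL_std": std,
        "SCL_fd_raw": fd_raw,
        "SCL_fd_norm": fd_norm,
        "SCL_sd_raw": sd_raw,
        "SCL_sd_norm": sd_norm,
        "SCL_n_max": float(len(kept_max)),
        "SCL_n_min": float(len(kept_min)),
        "SCL_n_extrema": float(len(kept_max) + len(kept_min)),
        "SCL_mean_amp_max": sum(kept_max) / len(kept_max) if kept_max else 0.0,
        "SCL_mean_amp_min": sum(kept_min) / len(kept_min) if kept_min else 0.0,
        "SCL_integral": integral,
        "SCL_slope": slope,
    }


def nn_series(intervals_ms):
    times = np.concatenate(([0.0], np.cumsum(intervals_ms) / 1000.0))
    return NNSeries(np.asarray(intervals_ms, dtype=float), times)


def scl_segment(x, fs=32.0, condition="neutral"):
    return Segment(np.asarray(x, dtype=float), fs, condition, np.asarray([x[0]]))


class TestHRV:
    def test_constant_series(self):
        f = pa.hrv_features(nn_series([800.0, 800.0, 800.0]))
        assert f["RMSSD"] == 0.0
        assert f["mean_RR"] == 800.0
        assert f["mean_HR"] == pytest.approx(75.0)
        assert f["std_RR"] == 0.0

    def test_single_difference(self):
        assert pa.hrv_features(nn_series([800.0, 850.0]))["RMSSD"] == pytest.approx(50.0)

    def test_four_interval_formula(self):
        f = pa.hrv_features(nn_series([700.0, 720.0, 710.0, 730.0]))
        assert f["RMSSD"] == pytest.approx(math.sqrt((400 + 100 + 400) / 3), abs=1e-4)
        assert f["RMSSD"] == pytest.approx(17.3205, abs=1e-4)

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            pa.hrv_features(nn_series([800.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-200, 500), seed=st.integers(0, 100))
    def test_shift_invariance(self, shift, seed):
        """RMSSD and std_RR are unchanged by adding a constant; mean_RR shifts by it."""
        base = np.random.default_rng(seed).uniform(600, 1000, size=12)
        f0 = pa.hrv_features(nn_series(base))
        f1 = pa.hrv_features(nn_series(base + shift))
        assert f1["RMSSD"] == pytest.approx(f0["RMSSD"], abs=1e-9)
        assert f1["std_RR"] == pytest.approx(f0["std_RR"], abs=1e-9)
        assert f1["mean_RR"] == pytest.approx(f0["mean_RR"] + shift, abs=1e-9)


class TestEMG:
    def test_block_minus_baseline(self):
        seg = Segment(np.full(100, 3.0), 32.0, "HVHA", np.full(64, 1.0))
        assert pa.emg_block_change(seg) == pytest.approx(2.0)
        seg_equal = Segment(np.full(100, 1.5), 32.0, "HVHA", np.full(64, 1.5))
        assert pa.emg_block_change(seg_equal) == 0.0

    def test_ramp_matches_mean_difference(self, rng):
        block = rng.uniform(0, 2, 200)
        baseline = rng.uniform(0, 1, 64)
        seg = Segment(block, 32.0, "LVLA", baseline)
        assert pa.emg_block_change(seg) == pytest.approx(block.mean() - baseline.mean())

    def test_empty_baseline(self):
        with pytest.raises(AlignmentError):
            pa.emg_block_change(Segment(np.ones(10), 32.0, "LVHA", np.empty(0)))

    def test_zscore_symmetric_triple(self):
        np.testing.assert_allclose(pa.zscore_within_subject([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_zscore_degenerate_all_equal(self):
        np.testing.assert_array_equal(pa.zscore_within_subject([4.0] * 5), np.zeros(5))

    def test_zscore_postconditions(self, rng):
        z = pa.zscore_within_subject(rng.normal(5, 3, size=10))
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zscore_single_block(self):
        with pytest.raises(InsufficientDataError):
            pa.zscore_within_subject([1.0])


class TestSCL:
    def test_constant_segment(self):
        f = pa.scl_features(scl_segment(np.full(640, 5.0)))
        assert f["SCL_mean"] == 5.0
        assert f["SCL_std"] == 0.0
        for k in ("SCL_fd_raw", "SCL_fd_norm", "SCL_sd_raw", "SCL_sd_norm"):
            assert f[k] == 0.0
        assert f["SCL_n_extrema"] == 0.0
        assert f["SCL_integral"] == pytest.approx((640 - 1) / 32.0 * 5.0)
        assert f["SCL_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp(self):
        n = 640  # 20 s at 32 Hz
        x = np.linspace(0.0, 2.0, n)
        f = pa.scl_features(scl_segment(x))
        duration = (n - 1) / 32.0
        assert f["SCL_slope"] == pytest.approx(2.0 / duration, rel=1e-9)
        assert f["SCL_n_max"] == 0.0 and f["SCL_n_min"] == 0.0
        assert f["SCL_integral"] == pytest.approx(duration * 1.0, rel=1e-9)  # mean 1 uS

    @pytest.mark.parametrize("height, expected", [(1.0, 1.0), (0.01, 0.0)])
    def test_bump_threshold(self, height, expected):
        x = np.full(200, 5.0)
        x[80:100] += np.linspace(0, height, 20)
        x[100:120] += np.linspace(height, 0, 20)
        f = pa.scl_features(scl_segment(x))
        assert f["SCL_n_max"] == expected
        if expected:
            assert f["SCL_mean_amp_max"] == pytest.approx(height, rel=1e-9)

    def test_too_short_segment(self):
        with pytest.raises(InsufficientDataError):
            pa.scl_features(scl_segment([1.0, 2.0]))

    def test_random_walk_matches_oracle(self, rng):
        x = 8.0 + np.cumsum(rng.normal(0, 0.05, 640))
        f = pa.scl_features(scl_segment(x))
        expected = oracle_scl(list(x), 32.0)
        for k, v in expected.items():
            assert f[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

    def test_integral_additive_over_partition(self, rng):
        x = rng.uniform(4, 6, 641)
        fs = 32.0
        whole = pa.scl_features(scl_segment(x, fs))["SCL_integral"]
        left = pa.scl_features(scl_segment(x[:321], fs))["SCL_integral"]
        right = pa.scl_features(scl_segment(x[320:], fs))["SCL_integral"]
        assert whole == pytest.approx(left + right, rel=1e-12)

    def test_threshold_monotonicity(self, rng):
        x = 8.0 + np.cumsum(rng.normal(0, 0.05, 640))
        counts = []
        for thr in (0.01, 0.05, 0.1, 0.2):
            f = pa.scl_features(scl_segment(x), amp_threshold=thr)
            counts.append((f["SCL_n_max"], f["SCL_n_min"]))
        for (m0, n0), (m1, n1) in zip(counts, counts[1:]):
            assert m1 <= m0 and n1 <= n0

    def test_extrema_count_identity(self, rng):
        for _ in range(20):
            x = 8.0 + np.cumsum(rng.normal(0, 0.1, 300))
            f = pa.scl_features(scl_segment(x))
            assert f["SCL_n_extrema"] == f["SCL_n_max"] + f["SCL_n_min"]


class TestAssemble:
    def _block_table(self, values_by_block):
        rows = []
        for i, v in enumerate(values_by_block):
            row = {"subject_id": "S000", "condition": "neutral" if i < 2 else "HVHA"}
            row.update({name: v for name in pa.FEATURE_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_two_blocks_average(self):
        table = self._block_table([1.0, 3.0, 5.0, 5.0])
        pooled = pa.assemble_feature_matrix(table)
        assert len(pooled) == 2
        neutral = pooled[pooled["condition"] == "neutral"].iloc[0]
        assert neutral["SCL_mean"] == pytest.approx(2.0)  # (1 + 3) / 2
        hvha = pooled[pooled["condition"] == "HVHA"].iloc[0]
        assert hvha["SCL_mean"] == pytest.approx(5.0)  # identical blocks -> either block

    def test_missing_column_rejected(self):
        table = self._block_table([1.0, 2.0]).drop(columns=["RMSSD"])
        with pytest.raises(CompletenessError):
            pa.assemble_feature_matrix(table)

    def test_missing_value_rejected(self):
        table = self._block_table([1.0, 2.0])
        table.loc[0, "SCL_mean"] = np.nan
        with pytest.raises(CompletenessError):
            pa.assemble_feature_matrix(table)

    def test_cohort_shape_and_invariants(self, small_cohort):
        """5 rows per subject; the SCL extrema identity holds row-wise."""
        matrix = small_cohort["matrix"]
        assert len(matrix) == 12 * 5
        counts = matrix.groupby("subject_id").size()
        assert (counts == 5).all()
        np.testing.assert_allclose(
            matrix["SCL_n_extrema"], matrix["SCL_n_max"] + matrix["SCL_n_min"]
        )
        nonneg = ["RMSSD", "std_RR", "std_HR", "SCL_std", "SCL_fd_raw", "SCL_fd_norm",
                  "SCL_sd_raw", "SCL_sd_norm", "SCL_mean_amp_max", "SCL_mean_amp_min"]
        assert (matrix[nonneg] >= 0).all().all()
        assert list(matrix.columns[2:]) == list(pa.FEATURE_NAMES)  # canonical order
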