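"""Signal matrix ingestion, coverage filtering, robust scaling, windowing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poremod import (
    FormatError,
    SignalMatrix,
    ValidationError,
    coverage_filter,
    preprocess,
    read_signal_tsv,
    window_features,
)
from poremod.signals import MAD_SCALE, robust_scale


def _matrix(records, ref_length=10, **kw):
    df = pd.DataFrame(records, columns=["read_id", "position", "dwell", "mean", "sd"])
    return SignalMatrix(df, ref_length=ref_length, **kw)


def _tsv(tmp_path, text, name="signal.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadSignalTsv:
    HEADER = "read_id\tposition\tdwell\tmean\tsd\n"

    def test_counts_records(self, tmp_path):
        body = "".join(
            f"r{i}\t{p}\t5.0\t0.1\t0.2\n" for i in range(2) for p in (1, 2, 3)
        )
        sm = read_signal_tsv(_tsv(tmp_path, self.HEADER + body))
        assert len(sm) == 6
        assert sm.n_reads == 2
        assert sm.ref_length == 3

    def test_missing_column_is_format_error(self, tmp_path):
        path = _tsv(tmp_path, "read_id\tposition\tdwell\tmean\nr1\t1\t5.0\t0.1\n")
        with pytest.raises(FormatError, match="sd"):
            read_signal_tsv(path)

    def test_duplicate_record_rejected(self, tmp_path):
        body = "r1\t1\t5.0\t0.1\t0.2\nr1\t1\t6.0\t0.1\t0.2\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_signal_tsv(_tsv(tmp_path, self.HEADER + body))

    def test_nonpositive_dwell_names_row(self, tmp_path):
        body = "r1\t1\t5.0\t0.1\t0.2\nr1\t2\t0.0\t0.1\t0.2\n"
        with pytest.raises(ValidationError, match="2"):
            read_signal_tsv(_tsv(tmp_path, self.HEADER + body))


class TestCoverageFilter:
    @staticmethod
    def _covering(read_id, n, ref_length):
        return [(read_id, p, 5.0, 0.0, 0.1) for p in range(1, n + 1)]

    def test_boundary_read_retained(self):
        sm = _matrix(self._covering("r1", 108, 120), ref_length=120)
        assert coverage_filter(sm, 0.9).n_reads == 1

    def test_short_read_dropped(self):
        sm = _matrix(self._covering("r1", 100, 120), ref_length=120)
        assert coverage_filter(sm, 0.9).n_reads == 0

    def test_full_coverage_only(self):
        records = self._covering("full", 120, 120) + self._covering("partial", 119, 120)
        sm = _matrix(records, ref_length=120)
        kept = coverage_filter(sm, 1.0)
        assert set(kept.df["read_id"]) == {"full"}


class TestRobustScale:
    def test_declared_constant(self):
        scaled, degenerate = robust_scale(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert not degenerate
        # median 3, MAD 1 -> 5 scales to 2 / 1.4826
        assert scaled[-1] == pytest.approx(2 / MAD_SCALE)
        assert scaled[-1] == pytest.approx(1.349, abs=1e-3)

    def test_constant_channel_falls_back_to_centering(self):
        scaled, degenerate = robust_scale(np.full(7, 3.5))
        assert degenerate
        assert np.allclose(scaled, 0.0)


class TestPreprocess:
    def test_pooled_median_of_scaled_channel_is_zero(self, null_bundle):
        mod, ctl, _ = preprocess(null_bundle.signal_modified, null_bundle.signal_control)
        pooled = pd.concat([mod.df, ctl.df])
        med = pooled.groupby("position")["mean"].median()
        assert np.allclose(med.to_numpy(), 0.0, atol=1e-12)

    def test_constant_channel_flagged(self):
        a = _matrix([("r%d" % i, 1, 2.0, 0.5, 0.1) for i in range(3)], ref_length=1)
        b = _matrix([("s%d" % i, 1, 2.0, 0.7, 0.1) for i in range(3)], ref_length=1)
        mod, ctl, warnings = preprocess(a, b)
        assert (1, "dwell") in warnings
        assert np.allclose(mod.df["dwell"], 0.0)

    def test_empty_sample_rejected(self):
        empty = _matrix([], ref_length=5)
        full = _matrix([("r1", 1, 2.0, 0.5, 0.1)], ref_length=5)
        with pytest.raises(ValidationError):
            preprocess(empty, full)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True)
    def test_scaling_preserves_order_per_channel(self, seed):
        rng = np.random.default_rng(seed)
        rec_a = [("a%d" % i, p, float(rng.lognormal(1, 0.5)), float(rng.normal()),
                  float(rng.gamma(2.0))) for i in range(5) for p in (1, 2)]
        rec_b = [("b%d" % i, p, float(rng.lognormal(1, 0.5)), float(rng.normal()),
                  float(rng.gamma(2.0))) for i in range(5) for p in (1, 2)]
        a, b = _matrix(rec_a, ref_length=2), _matrix(rec_b, ref_length=2)
        a2, b2, _ = preprocess(a, b)
        for raw, scaled in ((a, a2), (b, b2)):
            for pos in (1, 2):
                for ch in ("dwell", "mean", "sd"):
                    x = raw.df.loc[raw.df["position"] == pos, ch].to_numpy()
                    y = scaled.df.loc[scaled.df["position"] == pos, ch].to_numpy()
                    assert (np.argsort(x, kind="stable")
                            == np.argsort(y, kind="stable")).all()


class TestWindowFeatures:
    def _scaled(self, records, ref_length=6):
        return _matrix(records, ref_length=ref_length, preprocessed=True)

    def test_full_window_yields_one_vector(self):
        sm = self._scaled([("r1", p, 0.1 * p, 1.0 * p, 2.0 * p) for p in (4, 5, 6)])
        feats = window_features(sm, 5)
        assert feats.n == 1
        # ordering: (dwell, mean, sd) at 4, then 5, then 6
        expected = [0.4, 4.0, 8.0, 0.5, 5.0, 10.0, 0.6, 6.0, 12.0]
        assert np.allclose(feats.vectors[0], expected)

    def test_missing_center_excludes_read_from_three_windows(self):
        records = [("r1", p, 1.0, 0.0, 0.1) for p in (3, 4, 6, 7)]  # 5 deleted
        sm = self._scaled(records, ref_length=8)
        for center in (4, 5, 6):
            assert window_features(sm, center).n == 0
        assert window_features(sm, 3).n == 0  # needs 2,3,4 but 2 absent

    def test_edge_centers_are_undefined(self):
        sm = self._scaled([("r1", p, 1.0, 0.0, 0.1) for p in range(1, 7)])
        assert window_features(sm, 1) is None
        assert window_features(sm, 6) is None

    def test_vector_count_bounded_by_min_depth(self, default_bundle):
        sm = default_bundle.signal_modified
        dense = sm.to_dense()
        depth = {ch: (~np.isnan(arr)).sum(axis=0) for ch, arr in dense.items()}
        for center in (30, 60, 90):
            feats = window_features(sm, center, dense=dense)
            bound = min(depth["dwell"][center - 2:center + 1])
            assert feats.n <= bound


def test_tsv_round_trip(tmp_path, default_bundle):
    sm = default_bundle.signal_control
    path = tmp_path / "roundtrip.tsv"
    sm.to_tsv(path)
    again = read_signal_tsv(path, ref_length=sm.ref_length)
    assert again.equals(sm)
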