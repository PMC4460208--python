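import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dissogp as dg
from dissogp.datasets import (
    Dataset, DegenerateRangeError, FormatError, ScalingSpec, SplitError,
    ValidationError, VariableScale, grid_1d,
)


@pytest.fixture()
def csv_path(tmp_path, noiseless_ds):
    p = tmp_path / "dissolution.csv"
    dg.write_dissolution_csv(noiseless_ds, p)
    return p


class TestCsvIO:
    def test_roundtrip_preserves_study_counts(self, csv_path):
        ds = dg.read_dissolution_csv(csv_path)
        assert len(ds) == 1000
        assert len(ds.formulations) == 5
        assert ds.provenance == "original"

    def test_single_row_file(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("formulation_id,d_mm,L_mm,t_min,Q_pct\nF1,0.6,14,5,1.2\n")
        assert len(dg.read_dissolution_csv(p)) == 1

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(FormatError):
            dg.read_dissolution_csv(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("formulation_id,d_mm,t_min,Q_pct\nF1,0.6,5,1.2\n")
        with pytest.raises(FormatError, match="L_mm"):
            dg.read_dissolution_csv(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("formulation_id,d_mm,L_mm,t_min,Q_pct\n"
                     "F1,0.6,14,5,1.2\nF1,0.6,14,ten,2.0\n")
        with pytest.raises(ValidationError, match="row 1"):
            dg.read_dissolution_csv(p)

    def test_out_of_range_release_rejected(self, tmp_path):
        p = tmp_path / "range.csv"
        p.write_text("formulation_id,d_mm,L_mm,t_min,Q_pct\nF1,0.6,14,5,140\n")
        with pytest.raises(ValidationError, match="Q"):
            dg.read_dissolution_csv(p)


class TestScaling:
    def test_midpoint_maps_to_zero(self):
        vs = VariableScale(0.0, 100.0, -0.8, 0.8)
        assert vs.apply(50.0) == pytest.approx(0.0)
        assert vs.apply(0.0) == pytest.approx(-0.8)

    def test_roundtrip_identity(self, noisy_ds):
        spec = ScalingSpec.from_dataset(noisy_ds)
        back = dg.unscale_linear(dg.scale_linear(noisy_ds, spec))
        cols = ["d_mm", "L_mm", "t_min", "Q_pct"]
        assert np.allclose(back.df[cols], noisy_ds.df[cols],
                           rtol=1e-12, atol=1e-9)

    @given(lo=st.floats(-100, 100), span=st.floats(0.1, 200),
           v=st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_roundtrip_property(self, lo, span, v):
        vs = VariableScale(lo, lo + span, -0.8, 0.8)
        x = lo + v * span
        assert vs.invert(vs.apply(x)) == pytest.approx(x, abs=1e-9)

    def test_degenerate_source_range(self):
        with pytest.raises(DegenerateRangeError):
            VariableScale(5.0, 5.0, 0.0, 1.0)


class TestAddNoise:
    def test_zero_amplitude_copies_equal_originals(self, noiseless_ds):
        out = dg.add_noise(noiseless_ds, amplitude=0.0, seed=1)
        n = len(noiseless_ds)
        assert len(out) == 2 * n
        pd.testing.assert_frame_equal(
            out.df.iloc[n:].reset_index(drop=True).drop(columns="formulation_id"),
            noiseless_ds.df.drop(columns="formulation_id"))

    def test_jitter_stays_within_amplitude(self, noiseless_ds):
        out = dg.add_noise(noiseless_ds, amplitude=0.05, seed=2)
        n = len(noiseless_ds)
        for col in ("d_mm", "L_mm", "t_min", "Q_pct"):
            src = noiseless_ds.df[col].to_numpy()
            jit = out.df[col].to_numpy()[n:]
            assert np.all(jit >= src * 0.95 - 1e-12)
            assert np.all(jit <= src * 1.05 + 1e-12)

    def test_seeded_determinism(self, noiseless_ds):
        a = dg.add_noise(noiseless_ds, seed=7)
        b = dg.add_noise(noiseless_ds, seed=7)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_negative_amplitude_rejected(self, noiseless_ds):
        with pytest.raises(ValueError):
            dg.add_noise(noiseless_ds, amplitude=-0.1)


def _bin_counts(q, n_bins=10):
    lo, hi = q.min(), q.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(q, edges[1:-1]), 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


class TestBalance:
    def test_uniform_dataset_unchanged(self):
        q = np.tile(np.linspace(0, 100, 10), 5)
        df = pd.DataFrame({"formulation_id": "F1", "d_mm": 1.0, "L_mm": 1.0,
                           "t_min": np.arange(50.0), "Q_pct": q})
        out = dg.balance_by_output(Dataset(df))
        assert len(out) == 50

    def test_skewed_dataset_ratio_bounded(self, rng):
        # 90% of records above Q=80: the raw histogram is badly lopsided
        q = np.concatenate([rng.uniform(80, 100, 450), rng.uniform(0, 80, 50)])
        df = pd.DataFrame({"formulation_id": "F1", "d_mm": 1.0, "L_mm": 1.0,
                           "t_min": np.arange(500.0), "Q_pct": q})
        ds = Dataset(df)
        out = dg.balance_by_output(ds)
        counts = _bin_counts(out.df["Q_pct"].to_numpy())
        occupied = counts[counts > 0]
        assert occupied.max() / occupied.min() <= 2.0
        assert len(out) >= len(ds)  # never deletes
        assert set(out.df["Q_pct"]) == set(ds.df["Q_pct"])  # no invented values

    def test_single_value_dataset_warned_unchanged(self, caplog):
        df = pd.DataFrame({"formulation_id": "F1", "d_mm": 1.0, "L_mm": 1.0,
                           "t_min": np.arange(5.0), "Q_pct": 50.0})
        with caplog.at_level("WARNING"):
            out = dg.balance_by_output(Dataset(df))
        assert len(out) == 5


class TestSplit:
    def test_five_pairs_each_20_percent(self, noiseless_ds):
        folds = dg.split_leave_one_formulation_out(noiseless_ds)
        assert len(folds) == 5
        for f in folds:
            assert len(f.test) == 200
            assert len(f.test) / len(noiseless_ds) == pytest.approx(0.2)
            assert len(f.train) == 800

    def test_test_folds_partition_dataset(self, noiseless_ds):
        folds = dg.split_leave_one_formulation_out(noiseless_ds)
        held = [f.held_out_formulation for f in folds]
        assert sorted(held) == sorted(noiseless_ds.formulations)
        pooled = pd.concat([f.test.df for f in folds]).sort_values(
            ["formulation_id", "t_min"]).reset_index(drop=True)
        orig = noiseless_ds.df.sort_values(
            ["formulation_id", "t_min"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(pooled, orig)

    def test_single_formulation_refused(self, noiseless_ds):
        solo = Dataset(noiseless_ds.df[noiseless_ds.df.formulation_id == "F1"])
        with pytest.raises(SplitError):
            dg.split_leave_one_formulation_out(solo)


class TestEnhanced:
    @pytest.fixture()
    def fold(self, noiseless_ds):
        return dg.split_leave_one_formulation_out(noiseless_ds)[2]  # holds out F3

    @staticmethod
    def predictor(d, t):
        return 50.0 + 0.01 * t - d

    def test_grid_extends_to_110_percent(self, fold):
        out = dg.build_enhanced_dataset(fold.train, self.predictor, fold.test)
        aug = out.df[out.df.formulation_id.str.startswith("aug")]
        assert aug["d_mm"].max() == pytest.approx(1.10 * fold.train.df["d_mm"].max())
        assert aug["t_min"].max() <= 1.10 * fold.train.df["t_min"].max() + 1e-9

    def test_held_out_diameter_excluded(self, fold):
        out = dg.build_enhanced_dataset(fold.train, self.predictor, fold.test)
        aug = out.df[out.df.formulation_id.str.startswith("aug")]
        held_d = fold.test.df["d_mm"].iloc[0]
        assert np.all(np.abs(aug["d_mm"] - held_d) > 1e-9)

    def test_result_contains_training_records(self, fold):
        out = dg.build_enhanced_dataset(fold.train, self.predictor, fold.test)
        pd.testing.assert_frame_equal(out.df.iloc[:len(fold.train)],
                                      fold.train.df)

    def test_grid_count_matches_loop_oracle(self, fold):
        out = dg.build_enhanced_dataset(fold.train, self.predictor, fold.test)
        n_aug = len(out) - len(fold.train)

        def loop_grid(vmin, vmax, step_frac, extend):
            step = step_frac * (vmax - vmin)
            vals, v, k = [], vmin, 0
            while v <= extend * vmax + 1e-9 * step:
                vals.append(v)
                k += 1
                v = vmin + k * step
            if extend * vmax - vals[-1] > 1e-9 * step:
                vals.append(extend * vmax)  # boundary always sampled
            return vals

        d = fold.train.df["d_mm"]
        t = fold.train.df["t_min"]
        d_nodes = loop_grid(d.min(), d.max(), 0.0333, 1.10)
        t_nodes = loop_grid(t.min(), t.max(), 0.0333, 1.10)
        held_d = fold.test.df["d_mm"].iloc[0]
        d_kept = [v for v in d_nodes if abs(v - held_d) > 1e-9]
        assert n_aug == len(d_kept) * len(t_nodes)
        assert np.allclose(grid_1d(d.min(), d.max(), 0.0333, 1.10), d_nodes)
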