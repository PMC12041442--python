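import numpy as np
import pandas as pd
import pytest

from flushcurve.gompertz import gompertz
from flushcurve.simulate import (ExperimentDesign, FlushTruth, PauseSpec,
                                 default_flush_truths,
                                 evenly_spaced_flush_truths, load_config,
                                 read_yield_csv, simulate_bed_flush,
                                 simulate_experiment, validate_yield_table,
                                 write_yield_csv)


def noiseless_flush(A=1000.0, B=2.0, C=0.1):
    return FlushTruth(index=1, start_day=0, A_true={"X": A}, B_true={"X": B},
                      C_true=C, sigma_block=0, sigma_bed_A=0, sigma_bed_B=0,
                      noise_sd=0)


class TestBedFlush:
    def test_noiseless_total_reaches_asymptote(self):
        counts = simulate_bed_flush(noiseless_flush(), 1000.0, 2.0, 121, 0)
        assert abs(counts.sum() - 1000) <= 1

    def test_noiseless_cumulative_tracks_closed_form(self):
        """Carry-forward rounding keeps every day within one stem of the curve."""
        f = noiseless_flush()
        counts = simulate_bed_flush(f, 1000.0, 2.0, 121, 0)
        cum = np.cumsum(counts)
        expected = gompertz(np.arange(121), 1000.0, 2.0, 0.1)
        assert np.max(np.abs(cum - expected)) <= 1.0

    def test_inflection_value(self):
        # at t' = B/C = 20 the curve passes A/e ~ 367.9
        counts = simulate_bed_flush(noiseless_flush(), 1000.0, 2.0, 121, 0)
        assert abs(counts[:21].sum() - 1000 / np.e) <= 1.0

    def test_seeded_reproducibility(self):
        f = FlushTruth(index=1, start_day=0, A_true={"X": 1000}, B_true={"X": 2},
                       C_true=0.1, sigma_block=0, sigma_bed_A=0, sigma_bed_B=0,
                       noise_sd=5)
        a = simulate_bed_flush(f, 1000.0, 2.0, 100, 123)
        b = simulate_bed_flush(f, 1000.0, 2.0, 100, 123)
        c = simulate_bed_flush(f, 1000.0, 2.0, 100, 124)
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()

    def test_counts_are_nonnegative_integers(self):
        f = FlushTruth(index=1, start_day=0, A_true={"X": 500}, B_true={"X": 2},
                       C_true=0.1, sigma_block=0, sigma_bed_A=0, sigma_bed_B=0,
                       noise_sd=20)
        counts = simulate_bed_flush(f, 500.0, 2.0, 80, 5)
        assert counts.dtype.kind == "i"
        assert (counts >= 0).all()


class TestExperiment:
    def test_default_shape(self, default_dataset, design):
        t = default_dataset.yield_table
        assert t["bed_id"].nunique() == design.n_beds == 15
        assert t["day"].nunique() == design.horizon
        assert len(t) == design.n_beds * design.horizon

    def test_cumulative_invariants(self, default_dataset):
        for _, grp in default_dataset.yield_table.groupby("bed_id"):
            cum = grp.sort_values("day")["cumulative"].to_numpy()
            assert (np.diff(cum) >= 0).all()
            np.testing.assert_array_equal(
                cum, grp.sort_values("day")["stems"].cumsum().to_numpy())

    def test_no_harvest_before_first_flush(self, default_dataset):
        t = default_dataset.yield_table
        first = default_dataset.truth.flushes[0].start_day
        assert t.loc[t["day"] < first, "stems"].sum() == 0

    def test_overlapping_flush_windows_rejected(self, design):
        flushes = default_flush_truths(design)
        bad = [flushes[0], flushes[0]]
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate_experiment(design, bad, seed=0)

    def test_pause_zeroes_days_and_conserves_totals(self, design):
        pause = PauseSpec(201, 213, 220)
        plain = simulate_experiment(design, seed=3)
        paused = simulate_experiment(design, pause=pause, seed=3)
        tp = paused.yield_table
        assert tp.loc[tp["day"].between(201, 213), "stems"].sum() == 0
        for bed, grp in tp.groupby("bed_id"):
            ref = plain.yield_table[plain.yield_table["bed_id"] == bed]
            assert grp["stems"].sum() == ref["stems"].sum()

    def test_generator_mean_recovers_truth(self):
        """Mean realized asymptote over many seeds matches A_true within 2 SE."""
        design = ExperimentDesign(horizon=120)
        truth = FlushTruth(index=1, start_day=10,
                           A_true={t: 1000.0 for t in design.treatments},
                           B_true={t: 2.0 for t in design.treatments},
                           C_true=0.1, sigma_block=50, sigma_bed_A=80,
                           sigma_bed_B=0.1, noise_sd=5)
        per_seed = []
        for seed in range(100):
            ds = simulate_experiment(design, [truth], seed=seed)
            per_seed.append(ds.truth.bed_effects["realized_A"].mean())
        per_seed = np.asarray(per_seed)
        se = per_seed.std(ddof=1) / np.sqrt(len(per_seed))
        assert abs(per_seed.mean() - 1000.0) <= 2 * se + 1e-9

    def test_treatment_ordering_in_flush_totals(self):
        """A(Control) < A(R) in truth orders the mean flush totals over seeds."""
        design = ExperimentDesign(horizon=120)
        truth = FlushTruth(index=1, start_day=10,
                           A_true={"R": 1400.0, "T": 1200.0, "C": 1200.0,
                                   "R50": 1200.0, "Control": 1000.0},
                           B_true={t: 2.0 for t in design.treatments},
                           C_true=0.1, sigma_block=50, sigma_bed_A=80,
                           sigma_bed_B=0.1, noise_sd=5)
        tot_r, tot_ctl = [], []
        for seed in range(50):
            t = simulate_experiment(design, [truth], seed=seed).yield_table
            sums = t.groupby("treatment")["stems"].sum()
            tot_r.append(sums["R"])
            tot_ctl.append(sums["Control"])
        assert np.mean(tot_r) > np.mean(tot_ctl)

    def test_single_seed_governs_everything(self, design):
        a = simulate_experiment(design, seed=9).yield_table
        b = simulate_experiment(design, seed=9).yield_table
        pd.testing.assert_frame_equal(a, b)

    def test_evenly_spaced_preset_saturates_in_window(self):
        fl = evenly_spaced_flush_truths(gap=45)
        # ~98% of the asymptote is reached by the next start day
        f = fl[0]
        frac = gompertz(45.0, 1.0, f.B_true["R"], f.C_true)
        assert frac == pytest.approx(np.exp(-np.exp(-4.0)), rel=1e-12)


class TestYieldCsv:
    def test_round_trip(self, default_dataset, tmp_path):
        p = tmp_path / "y.csv"
        write_yield_csv(default_dataset, p)
        back = read_yield_csv(p)
        pd.testing.assert_frame_equal(
            back, default_dataset.yield_table, check_dtype=False)

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"bed_id": ["b"] * 3, "block_id": ["B1"] * 3,
                      "treatment": ["R"] * 3, "day": [0, 1, 2],
                      "stems": [1, -1, 2]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="non-negative"):
            read_yield_csv(p)

    def test_gap_day_rejected_with_location(self, tmp_path):
        p = tmp_path / "gap.csv"
        pd.DataFrame({"bed_id": ["b"] * 3, "block_id": ["B1"] * 3,
                      "treatment": ["R"] * 3, "day": [0, 1, 3],
                      "stems": [1, 1, 1]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="gap between day 1 and day 3"):
            read_yield_csv(p)

    def test_duplicate_day_rejected(self):
        t = pd.DataFrame({"bed_id": ["b"] * 2, "block_id": ["B1"] * 2,
                          "treatment": ["R"] * 2, "day": [0, 0], "stems": [1, 1]})
        with pytest.raises(ValueError, match="duplicate"):
            validate_yield_table(t)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_yield_table(pd.DataFrame({"bed_id": [], "day": []}))


def test_yaml_config_round_trip(tmp_path):
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "design: {n_blocks: 2, treatments: [A1, A2], horizon: 120}\n"
        "flushes:\n"
        "  - {index: 1, start_day: 10, A: {A1: 800, A2: 900},\n"
        "     B: {A1: 2.0, A2: 2.1}, C: 0.09, noise_sd: 0,\n"
        "     sigma_block: 0, sigma_bed_A: 0, sigma_bed_B: 0}\n"
        "pause: {pause_start: 40, pause_end: 50, catchup_end: 55}\n"
    )
    design, flushes, pause = load_config(cfg)
    assert design.n_blocks == 2 and design.treatments == ("A1", "A2")
    assert flushes[0].A_true == {"A1": 800, "A2": 900}
    assert pause == PauseSpec(40, 50, 55)
    ds = simulate_experiment(design, flushes, pause=pause, seed=0)
    assert ds.yield_table["bed_id"].nunique() == 4
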