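"""Synthetic multi-flush rose-yield experiments with known ground truth.

Emulates a randomized-block greenhouse trial: five compost treatments times
three blocks equals fifteen beds of ~500 plants, harvested daily over an
18-month horizon.  Yield arrives in ~8 successive flowering flushes, each a
Gompertz-shaped rise in cumulative stems.  Treatments shift the per-flush
asymptote A and growth-rate parameter B; blocks and beds add normal random
effects; daily counts are integer with carry-forward rounding so cumulative
series stay monotone and flush totals match the realized asymptote.

An optional harvest-pause artifact (a run of zero-harvest days followed by a
catch-up period that carries the deferred stems) reproduces the kind of
operational disturbance real harvest records contain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .gompertz import gompertz

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentDesign",
    "FlushTruth",
    "PauseSpec",
    "SimulationTruth",
    "SyntheticDataset",
    "default_flush_truths",
    "simulate_bed_flush",
    "simulate_experiment",
    "validate_yield_table",
    "add_cumulative",
    "write_yield_csv",
    "read_yield_csv",
    "load_config",
]

DEFAULT_TREATMENTS = ("R", "T", "C", "R50", "Control")

YIELD_COLUMNS = ["bed_id", "block_id", "treatment", "day", "stems"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Randomized block design: one bed per (block, treatment) pair."""

    n_blocks: int = 3
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    plants_per_bed: int = 500
    planting_day: int = 0
    horizon: int = 560

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not self.treatments:
            raise ValueError("treatments must be non-empty")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatment labels must be unique")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def n_beds(self) -> int:
        return self.n_blocks * len(self.treatments)

    def beds(self) -> list[tuple[str, str, str]]:
        """(bed_id, block_id, treatment) for every bed."""
        out = []
        for b in range(1, self.n_blocks + 1):
            block_id = f"B{b}"
            for trt in self.treatments:
                out.append((f"{block_id}_{trt}", block_id, trt))
        return out


@dataclass(frozen=True)
class FlushTruth:
    """Generating parameters of one flowering flush (1-based index)."""

    index: int
    start_day: int
    A_true: Mapping[str, float]
    B_true: Mapping[str, float]
    C_true: float = 0.1
    sigma_block: float = 50.0   # SD of block random effect on A, stems
    sigma_bed_A: float = 80.0   # SD of bed random effect on A, stems
    sigma_bed_B: float = 0.1    # SD of bed random effect on B
    noise_sd: float = 5.0       # daily observation noise (stems) before rounding

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.A_true.values()):
            raise ValueError(f"flush {self.index}: A_true must be positive")
        if self.C_true <= 0:
            raise ValueError(f"flush {self.index}: C_true must be positive")
        for name in ("sigma_block", "sigma_bed_A", "sigma_bed_B", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"flush {self.index}: {name} must be >= 0")


@dataclass(frozen=True)
class PauseSpec:
    """Harvest-pause artifact: zero harvest then catch-up, day indices inclusive."""

    pause_start: int
    pause_end: int
    catchup_end: int

    def __post_init__(self) -> None:
        if not (self.pause_start < self.pause_end <= self.catchup_end):
            raise ValueError(
                "require pause_start < pause_end <= catchup_end, got "
                f"({self.pause_start}, {self.pause_end}, {self.catchup_end})"
            )


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic experiment, retained for recovery tests."""

    design: ExperimentDesign
    flushes: list[FlushTruth]
    block_effects: pd.DataFrame  # flush, block_id, effect_A
    bed_effects: pd.DataFrame    # flush, bed_id, effect_A, effect_B, realized A/B
    pause: PauseSpec | None
    seed: int

    def realized_params(self, flush_index: int) -> pd.DataFrame:
        """Per-bed realized (A, B) for one flush."""
        df = self.bed_effects
        return df[df["flush"] == flush_index].reset_index(drop=True)


@dataclass
class SyntheticDataset:
    yield_table: pd.DataFrame
    truth: SimulationTruth


def default_flush_truths(
    design: ExperimentDesign | None = None,
    noise_sd: float = 5.0,
    sigma_block: float = 50.0,
    sigma_bed_A: float = 80.0,
    sigma_bed_B: float = 0.1,
) -> list[FlushTruth]:
    """Default 8-flush truth trajectory.

    Asymptotes rise from ~1000 stems in the young crop to ~3300 at maturity
    with a dip in the final flush; B is low in the short first flush, peaks
    in flush 2, then declines as flushes blur together; C is constant at 0.1
    per day.  Compost treatments (R, T, C) gain ~300 stems early, fading as
    the crop matures; the half-fertigation treatment (R50) keeps pace through
    flush 4 and then falls back to the untreated control.
    """
    design = design or ExperimentDesign()
    starts = [91, 129, 186, 240, 302, 363, 426, 490]
    a_base = [950.0, 1150.0, 1400.0, 2600.0, 2900.0, 3100.0, 3300.0, 2900.0]
    b_base = [2.0, 3.0, 2.9, 2.7, 2.5, 2.4, 2.2, 2.1]
    compost_a = [300.0, 300.0, 320.0, 350.0, 300.0, 250.0, 80.0, 60.0]
    r50_a = [280.0, 300.0, 300.0, 250.0, 80.0, 40.0, 20.0, 0.0]
    compost_b = [0.15, 0.15, 0.15, 0.15, 0.12, 0.10, 0.05, 0.0]
    r50_b = [0.12, 0.12, 0.10, 0.08, 0.0, 0.0, 0.0, 0.0]

    def a_for(trt: str, k: int) -> float:
        if trt in ("R", "T", "C"):
            tweak = {"R": 0.0, "T": -30.0, "C": -15.0}[trt]
            return a_base[k] + compost_a[k] + tweak
        if trt == "R50":
            return a_base[k] + r50_a[k]
        return a_base[k]

    def b_for(trt: str, k: int) -> float:
        if trt in ("R", "T", "C"):
            return b_base[k] + compost_b[k]
        if trt == "R50":
            return b_base[k] + r50_b[k]
        return b_base[k]

    flushes = []
    for k, start in enumerate(starts):
        flushes.append(
            FlushTruth(
                index=k + 1,
                start_day=start,
                A_true={t: a_for(t, k) for t in design.treatments},
                B_true={t: b_for(t, k) for t in design.treatments},
                C_true=0.1,
                sigma_block=sigma_block,
                sigma_bed_A=sigma_bed_A,
                sigma_bed_B=sigma_bed_B,
                noise_sd=noise_sd,
            )
        )
    return flushes


def evenly_spaced_flush_truths(
    design: ExperimentDesign | None = None,
    n_flushes: int = 8,
    first_start: int = 91,
    gap: int = 45,
    A: float = 2000.0,
    B: float = 2.5,
    treatment_step_A: float = 100.0,
    noise_sd: float = 0.0,
    sigma_block: float = 0.0,
    sigma_bed_A: float = 0.0,
    sigma_bed_B: float = 0.0,
) -> list[FlushTruth]:
    """Regularly spaced flushes that saturate within their windows.

    C is set to (B + 4) / gap so each Gompertz curve is ~98% complete at the
    next start day.  With B around 2.5 the decaying tail of one flush and
    the onset of the next balance, so the pooled harvest-rate minimum falls
    on the generative start day itself — the start days are identifiable,
    not truncation artifacts.  Treatments receive asymptotes A, A + step,
    A + 2*step, ... in design order.  Intended for boundary-recovery
    studies; the irregular default trajectory is the realistic study
    emulation.
    """
    design = design or ExperimentDesign()
    C = (B + 4.0) / gap
    starts = [first_start + k * gap for k in range(n_flushes)]
    if starts[-1] + gap > design.horizon:
        raise ValueError("flushes exceed horizon; reduce n_flushes or gap")
    out = []
    for k, s in enumerate(starts):
        out.append(
            FlushTruth(
                index=k + 1,
                start_day=s,
                A_true={t: A + j * treatment_step_A for j, t in enumerate(design.treatments)},
                B_true={t: B for t in design.treatments},
                C_true=C,
                sigma_block=sigma_block,
                sigma_bed_A=sigma_bed_A,
                sigma_bed_B=sigma_bed_B,
                noise_sd=noise_sd,
            )
        )
    return out


def simulate_bed_flush(
    flush: FlushTruth,
    a_realized: float,
    b_realized: float,
    n_days: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Integer daily stem counts for one bed over one flush.

    The expected cumulative curve is ``a * exp(-exp(b - C*t'))`` for
    t' = 0..n_days-1.  Daily increments receive differenced normal noise
    (SD ``flush.noise_sd`` on the cumulative trajectory): a noisy day is
    compensated on the following days, so the perturbation never integrates
    and the flush total stays anchored to the realized asymptote.  Counts
    are emitted by carry-forward rounding of the monotone noisy target —
    each day's count is the rounded target minus what has already been
    emitted — keeping them non-negative integers with at most half a stem
    of accumulated rounding error.
    """
    if a_realized <= 0:
        raise ValueError(f"realized asymptote must be positive, got {a_realized}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    tprime = np.arange(n_days, dtype=float)
    target = gompertz(tprime, a_realized, b_realized, flush.C_true)
    if flush.noise_sd > 0:
        target = target + rng.normal(0.0, flush.noise_sd, size=n_days)
    s = np.maximum.accumulate(target)
    cum = np.rint(np.maximum(s, 0.0)).astype(np.int64)
    return np.diff(cum, prepend=np.int64(0))


def _check_flush_windows(flushes: Sequence[FlushTruth], horizon: int) -> None:
    starts = [f.start_day for f in flushes]
    if any(s2 <= s1 for s1, s2 in zip(starts, starts[1:])):
        raise ValueError(f"flush start days must be strictly increasing, got {starts}")
    if starts and (starts[0] < 0 or starts[-1] >= horizon):
        raise ValueError(f"flush start days {starts} outside horizon [0, {horizon})")


def simulate_experiment(
    design: ExperimentDesign | None = None,
    flushes: Sequence[FlushTruth] | None = None,
    pause: PauseSpec | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a full randomized-block experiment.

    A single seed governs everything; per-bed noise substreams are spawned
    deterministically from it so any bed's series can be re-simulated without
    running the rest.  Random effects are drawn independently per flush
    (block effect on A; bed effects on A and B); a bed whose realized
    asymptote would be non-positive is redrawn with a logged warning.
    """
    design = design or ExperimentDesign()
    flushes = list(flushes) if flushes is not None else default_flush_truths(design)
    _check_flush_windows(flushes, design.horizon)
    for f in flushes:
        missing = set(design.treatments) - set(f.A_true) | set(design.treatments) - set(f.B_true)
        if missing:
            raise ValueError(f"flush {f.index}: missing treatment parameters {sorted(missing)}")
    if pause is not None and pause.catchup_end >= design.horizon:
        raise ValueError("pause window must lie within the horizon")

    ss = np.random.SeedSequence(seed)
    eff_child, bed_child = ss.spawn(2)
    eff_rng = np.random.default_rng(eff_child)
    beds = design.beds()
    bed_rngs = {bid: np.random.default_rng(child) for (bid, _, _), child in zip(beds, bed_child.spawn(len(beds)))}

    starts = [f.start_day for f in flushes]
    ends = starts[1:] + [design.horizon]

    block_rows, bed_rows = [], []
    counts = {bid: np.zeros(design.horizon, dtype=np.int64) for bid, _, _ in beds}

    for flush, end in zip(flushes, ends):
        n_days = end - flush.start_day
        u_block = {
            f"B{b}": eff_rng.normal(0.0, flush.sigma_block) if flush.sigma_block > 0 else 0.0
            for b in range(1, design.n_blocks + 1)
        }
        for block_id, eff in u_block.items():
            block_rows.append({"flush": flush.index, "block_id": block_id, "effect_A": eff})
        for bed_id, block_id, trt in beds:
            for _attempt in range(100):
                vA = eff_rng.normal(0.0, flush.sigma_bed_A) if flush.sigma_bed_A > 0 else 0.0
                vB = eff_rng.normal(0.0, flush.sigma_bed_B) if flush.sigma_bed_B > 0 else 0.0
                a_i = flush.A_true[trt] + u_block[block_id] + vA
                b_i = flush.B_true[trt] + vB
                if a_i > 0:
                    break
                logger.warning(
                    "flush %d bed %s: non-positive realized asymptote %.1f, redrawing",
                    flush.index, bed_id, a_i,
                )
            else:
                raise RuntimeError(f"could not draw positive asymptote for bed {bed_id}")
            bed_rows.append(
                {
                    "flush": flush.index, "bed_id": bed_id, "block_id": block_id,
                    "treatment": trt, "effect_A": vA, "effect_B": vB,
                    "realized_A": a_i, "realized_B": b_i,
                }
            )
            daily = simulate_bed_flush(flush, a_i, b_i, n_days, bed_rngs[bed_id])
            counts[bed_id][flush.start_day:end] = daily

    if pause is not None:
        for bed_id in counts:
            _apply_pause_inplace(counts[bed_id], pause)

    records = []
    for bed_id, block_id, trt in beds:
        c = counts[bed_id]
        records.append(
            pd.DataFrame(
                {
                    "bed_id": bed_id,
                    "block_id": block_id,
                    "treatment": trt,
                    "day": np.arange(design.horizon),
                    "stems": c,
                }
            )
        )
    table = add_cumulative(pd.concat(records, ignore_index=True))
    truth = SimulationTruth(
        design=design,
        flushes=flushes,
        block_effects=pd.DataFrame(block_rows),
        bed_effects=pd.DataFrame(bed_rows),
        pause=pause,
        seed=seed,
    )
    return SyntheticDataset(yield_table=table, truth=truth)


def _apply_pause_inplace(daily: np.ndarray, pause: PauseSpec) -> None:
    """Zero the pause days, then spread the withheld stems over the catch-up
    window (earliest days absorb the remainder); totals conserved exactly."""
    withheld = int(daily[pause.pause_start : pause.pause_end + 1].sum())
    daily[pause.pause_start : pause.pause_end + 1] = 0
    catchup = np.arange(pause.pause_end + 1, pause.catchup_end + 1)
    base, rem = divmod(withheld, len(catchup))
    daily[catchup] += base
    daily[catchup[:rem]] += 1


# ---------------------------------------------------------------------------
# yield-table container helpers and I/O


def add_cumulative(table: pd.DataFrame) -> pd.DataFrame:
    """Sort by (bed_id, day) and (re)compute the per-bed cumulative column."""
    out = table.sort_values(["bed_id", "day"], kind="stable").reset_index(drop=True)
    out["cumulative"] = out.groupby("bed_id", sort=False)["stems"].cumsum()
    return out


def validate_yield_table(table: pd.DataFrame) -> None:
    """Check the yield-table invariants, naming the offending rows.

    Requires the long-format columns bed_id, block_id, treatment, day, stems;
    integer non-negative counts; no duplicate (bed, day) rows; and gap-free
    daily coverage per bed.
    """
    missing = [c for c in YIELD_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"yield table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("yield table is empty")
    stems = table["stems"]
    bad = table[(stems < 0) | (stems != stems.astype(np.int64))]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"stems must be non-negative integers; offending row: bed {row['bed_id']} "
            f"day {int(row['day'])} stems {row['stems']}"
        )
    dup = table.duplicated(subset=["bed_id", "day"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(f"duplicate (bed, day) row: bed {row['bed_id']} day {int(row['day'])}")
    for bed_id, grp in table.groupby("bed_id"):
        days = np.sort(grp["day"].to_numpy())
        gaps = np.flatnonzero(np.diff(days) != 1)
        if len(gaps):
            raise ValueError(
                f"bed {bed_id}: day coverage has a gap between day {int(days[gaps[0]])} "
                f"and day {int(days[gaps[0] + 1])}"
            )


def write_yield_csv(dataset: SyntheticDataset | pd.DataFrame, path: str | Path,
                    truth_path: str | Path | None = None) -> None:
    """Write the long-format yield table (and optionally a truth JSON sidecar)."""
    table = dataset.yield_table if isinstance(dataset, SyntheticDataset) else dataset
    table[YIELD_COLUMNS].to_csv(path, index=False)
    if truth_path is not None:
        if not isinstance(dataset, SyntheticDataset):
            raise ValueError("truth sidecar requested but no SyntheticDataset given")
        write_truth_json(dataset.truth, truth_path)


def read_yield_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a yield CSV; returns the table with a cumulative column."""
    table = pd.read_csv(path)
    validate_yield_table(table)
    table["day"] = table["day"].astype(np.int64)
    table["stems"] = table["stems"].astype(np.int64)
    return add_cumulative(table)


def write_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "design": asdict(truth.design),
        "pause": asdict(truth.pause) if truth.pause else None,
        "flushes": [
            {**asdict(f), "A_true": dict(f.A_true), "B_true": dict(f.B_true)}
            for f in truth.flushes
        ],
        "block_effects": truth.block_effects.to_dict(orient="records"),
        "bed_effects": truth.bed_effects.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    d = payload["design"]
    design = ExperimentDesign(
        n_blocks=d["n_blocks"], treatments=tuple(d["treatments"]),
        plants_per_bed=d["plants_per_bed"], planting_day=d["planting_day"],
        horizon=d["horizon"],
    )
    pause = PauseSpec(**payload["pause"]) if payload["pause"] else None
    flushes = [FlushTruth(**f) for f in payload["flushes"]]
    return SimulationTruth(
        design=design, flushes=flushes,
        block_effects=pd.DataFrame(payload["block_effects"]),
        bed_effects=pd.DataFrame(payload["bed_effects"]),
        pause=pause, seed=payload["seed"],
    )


def load_config(path: str | Path) -> tuple[ExperimentDesign, list[FlushTruth], PauseSpec | None]:
    """Load (design, flush truths, pause) from a YAML config file.

    ``flushes`` may be omitted to take the default trajectory; per-flush keys
    mirror FlushTruth fields, with A/B given as treatment -> value mappings.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    dcfg = cfg.get("design", {})
    if "treatments" in dcfg:
        dcfg["treatments"] = tuple(dcfg["treatments"])
    design = ExperimentDesign(**dcfg)
    if "flushes" in cfg:
        flushes = [
            FlushTruth(
                index=f["index"], start_day=f["start_day"],
                A_true=dict(f["A"]), B_true=dict(f["B"]),
                C_true=f.get("C", 0.1),
                sigma_block=f.get("sigma_block", 50.0),
                sigma_bed_A=f.get("sigma_bed_A", 80.0),
                sigma_bed_B=f.get("sigma_bed_B", 0.1),
                noise_sd=f.get("noise_sd", 5.0),
            )
            for f in cfg["flushes"]
        ]
    else:
        flushes = default_flush_truths(design)
    pause = PauseSpec(**cfg["pause"]) if cfg.get("pause") else None
    return design, flushes, pause
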