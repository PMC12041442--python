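"""End-to-end pipeline: segment flushes, fit both model families, report.

Orchestrates pool -> segment -> split -> weight -> fit (Gompertz NLME and
additive-mixed benchmark per flush) -> tables, with per-flush failure
isolation: one pathological flush is logged and skipped rather than killing
the run.  Every run records provenance (config hash, seed, package version)
and is reproducible from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gamm import FlushGAMM, FlushGAMMResults, GammConfig, compare_fits
from .nlme import (GompertzMixedModel, GompertzMixedResults, NlmeSpec,
                   contrast_vs_control, treatment_table)
from .segmentation import (FlushBoundaries, SegmentationConfig, build_weights,
                           segment, split_flushes)
from .simulate import (ExperimentDesign, FlushTruth, PauseSpec,
                       read_yield_csv, simulate_experiment)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "trajectory_table",
           "plot_outputs"]


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_csv`` (observed data) or ``design`` (synthetic
    experiment, optionally with explicit flush truths) must be given.
    """

    input_csv: str | Path | None = None
    design: ExperimentDesign | None = None
    flush_truths: list[FlushTruth] | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    nlme: NlmeSpec = field(default_factory=NlmeSpec)
    gamm: GammConfig = field(default_factory=GammConfig)
    pause: PauseSpec | None = None
    control_label: str = "Control"
    fit_method: str = "saem"
    output_dir: str | Path | None = None
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.design is None):
            raise ValueError("give exactly one of input_csv or design")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, Path):
                return str(o)
            return o
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    boundaries: FlushBoundaries
    flush_table: pd.DataFrame
    gompertz_fits: dict[int, GompertzMixedResults]
    gamm_fits: dict[int, FlushGAMMResults]
    failures: dict[int, str]
    treatment_table: pd.DataFrame | None
    contrast_table: pd.DataFrame | None
    comparison: pd.DataFrame | None
    provenance: dict

    @property
    def n_flushes(self) -> int:
        return int(self.flush_table["flush"].nunique())


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; artifacts written to ``config.output_dir``."""
    if config.input_csv is not None:
        table = read_yield_csv(config.input_csv)
    else:
        ds = simulate_experiment(config.design, config.flush_truths,
                                 pause=config.pause, seed=config.seed)
        table = ds.yield_table

    boundaries = segment(table, config.segmentation)
    flush_table = split_flushes(table, boundaries)

    gomp_fits: dict[int, GompertzMixedResults] = {}
    gamm_fits: dict[int, FlushGAMMResults] = {}
    failures: dict[int, str] = {}
    comp_rows = []
    for k in sorted(flush_table["flush"].unique()):
        sub = flush_table[flush_table["flush"] == k]
        w = build_weights(sub, config.pause)
        try:
            spec = dataclasses.replace(config.nlme, seed=config.seed + int(k))
            gomp = GompertzMixedModel(sub, weights=w, spec=spec,
                                      flush=int(k)).fit(method=config.fit_method)
            gomp_fits[int(k)] = gomp
        except Exception as exc:  # noqa: BLE001 - logged, run continues
            failures[int(k)] = f"gompertz: {exc}"
            logger.warning("flush %s Gompertz fit failed: %s", k, exc)
            continue
        try:
            gm = FlushGAMM(sub, config=config.gamm, flush=int(k)).fit()
            gamm_fits[int(k)] = gm
            _, summ = compare_fits(gm, gomp)
            comp_rows.append({"flush": int(k), **summ,
                              "gamm_r2": gm.efron_r2, "gompertz_r2": gomp.efron_r2})
        except Exception as exc:  # noqa: BLE001
            failures[int(k)] = f"gamm: {exc}"
            logger.warning("flush %s benchmark fit failed: %s", k, exc)

    fits = list(gomp_fits.values())
    ttable = treatment_table(fits) if fits else None
    ctable = (contrast_vs_control(fits, control=config.control_label)
              if fits and any(config.control_label in f.model.treatments for f in fits)
              else None)
    comparison = pd.DataFrame(comp_rows) if comp_rows else None

    report = RunReport(
        boundaries=boundaries, flush_table=flush_table,
        gompertz_fits=gomp_fits, gamm_fits=gamm_fits, failures=failures,
        treatment_table=ttable, contrast_table=ctable, comparison=comparison,
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__,
                    "boundary_days": list(boundaries.boundary_days)},
    )
    if config.output_dir is not None:
        _write_artifacts(report, Path(config.output_dir), config)
    return report


def _write_artifacts(report: RunReport, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"boundary_day": report.boundaries.boundary_days}).to_csv(
        outdir / "boundaries.csv", index=False)
    if report.boundaries.per_bed_offsets is not None:
        report.boundaries.per_bed_offsets.to_csv(outdir / "flush_offsets.csv", index=False)
    if report.treatment_table is not None:
        report.treatment_table.to_csv(outdir / "treatment_estimates.csv", index=False)
    if report.contrast_table is not None:
        report.contrast_table.to_csv(outdir / "contrasts_vs_control.csv", index=False)
    if report.comparison is not None:
        report.comparison.to_csv(outdir / "model_comparison.csv", index=False)
    diag = {
        "provenance": report.provenance,
        "failures": report.failures,
        "fits": {
            str(k): {
                "method": f.method, "converged": f.converged,
                "efron_r2": float(f.efron_r2), "scale": f.scale,
                "vcomp": f.vcomp,
            } for k, f in report.gompertz_fits.items()
        },
        "gamm": {
            str(k): {"aic": f.aic, "efron_r2": float(f.efron_r2)}
            for k, f in report.gamm_fits.items()
        },
    }
    (outdir / "run_report.json").write_text(json.dumps(diag, indent=1))
    if config.make_plots:
        plot_outputs(report, outdir)


def trajectory_table(report: RunReport) -> tuple[pd.DataFrame, dict]:
    """A and B versus flush index per treatment, with qualitative flags.

    Flags: ``A_increasing_early`` — for every treatment, A rises from the
    first to the mid flushes; ``B_declining`` — B decreases from its peak
    flush to the last flush for every treatment.  Missing flushes are
    reported in the flags.
    """
    tt = report.treatment_table
    if tt is None or tt["flush"].nunique() < 2:
        raise ValueError("need fits for at least 2 flushes")
    traj = tt[tt["parameter"].isin(["A", "B"])].copy()
    flushes = sorted(traj["flush"].unique())
    expected = set(range(min(flushes), max(flushes) + 1))
    gaps = sorted(expected - set(flushes))

    a_flags, b_flags = [], []
    mid = flushes[min(len(flushes) - 1, 3)]
    for trt, grp in traj[traj["parameter"] == "A"].groupby("treatment"):
        grp = grp.set_index("flush")["estimate"]
        if flushes[0] in grp.index and mid in grp.index:
            a_flags.append(grp.loc[mid] > grp.loc[flushes[0]])
    for trt, grp in traj[traj["parameter"] == "B"].groupby("treatment"):
        grp = grp.set_index("flush")["estimate"]
        b_flags.append(grp.loc[flushes[-1]] < grp.max())
    flags = {
        "A_increasing_early": bool(a_flags and all(a_flags)),
        "B_declining": bool(b_flags and all(b_flags)),
        "missing_flushes": gaps,
    }
    return traj.reset_index(drop=True), flags


def plot_outputs(report: RunReport, directory: str | Path) -> list[Path]:
    """Optional figures: per-flush fit overlays, trajectories, contrasts.

    Never raises: if the plotting backend is unavailable the run proceeds
    with a warning.  Filenames are deterministic, keyed by flush index.
    """
    try:
        import matplotlib
        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt
    except Exception as exc:  # noqa: BLE001
        warnings.warn(f"plotting backend unavailable, skipping figures: {exc}")
        return []
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not report.gompertz_fits:
        warnings.warn("empty report: no figures written")
        return []

    for k, fit in sorted(report.gompertz_fits.items()):
        fig, ax = plt.subplots(figsize=(6, 4))
        data = fit.model.data
        for trt, grp in data.groupby("treatment"):
            ax.scatter(grp["t_prime"], grp["y_prime"], s=4, alpha=0.4, label=None)
        order = np.argsort(fit.model.t)
        ax.plot(fit.model.t[order], fit.fittedvalues[order], ".", ms=2, color="k")
        ax.set_xlabel("days since flush start")
        ax.set_ylabel("cumulative stems (flush-relative)")
        ax.set_title(f"Flush {k}: Gompertz fit (R2={fit.efron_r2:.3f})")
        p = directory / f"flush_{k:02d}_fit.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

    try:
        traj, _ = trajectory_table(report)
        for param in ("A", "B"):
            fig, ax = plt.subplots(figsize=(6, 4))
            for trt, grp in traj[traj["parameter"] == param].groupby("treatment"):
                ax.errorbar(grp["flush"], grp["estimate"], yerr=grp["se"],
                            marker="o", label=str(trt))
            ax.set_xlabel("flush")
            ax.set_ylabel(param)
            ax.legend(fontsize=7)
            p = directory / f"trajectory_{param}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written.append(p)
    except ValueError:
        pass

    if report.contrast_table is not None:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, param in zip(axes, ("A", "B")):
            sub = report.contrast_table[report.contrast_table["parameter"] == param]
            for trt, grp in sub.groupby("treatment"):
                ax.errorbar(grp["flush"], grp["difference"],
                            yerr=1.96 * grp["se"], marker="o", label=str(trt))
            ax.axhline(0, color="gray", lw=0.5)
            ax.set_xlabel("flush")
            ax.set_ylabel(f"difference in {param} vs control")
            ax.legend(fontsize=7)
        p = directory / "contrasts.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
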