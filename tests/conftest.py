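import dataclasses

import numpy as np
import pytest

from flushcurve.segmentation import (FlushBoundaries, SegmentationConfig,
                                     split_flushes)
from flushcurve.simulate import (ExperimentDesign, FlushTruth,
                                 default_flush_truths, simulate_experiment)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def default_dataset(design):
    """One realistic synthetic experiment (8 flushes, default noise)."""
    return simulate_experiment(design, seed=42)


@pytest.fixture(scope="session")
def true_boundaries(default_dataset):
    """Boundaries taken from the generating truth, not from detection."""
    days = [f.start_day for f in default_dataset.truth.flushes][1:]
    return FlushBoundaries(boundary_days=days, config=SegmentationConfig())


@pytest.fixture(scope="session")
def flush_table(default_dataset, true_boundaries):
    return split_flushes(default_dataset.yield_table, true_boundaries)


def single_flush_dataset(seed, noise_sd=5.0, sigma_block=50.0, sigma_bed_A=80.0,
                         sigma_bed_B=0.1, A_base=2600.0, A_step=100.0,
                         B_base=2.7, B_step=0.04, C=0.1, duration=62):
    """One-flush experiment with per-treatment A/B steps; returns (dataset, truth)."""
    design = ExperimentDesign(horizon=20 + duration)
    truth = FlushTruth(
        index=1, start_day=20,
        A_true={t: A_base + i * A_step for i, t in enumerate(design.treatments)},
        B_true={t: B_base + i * B_step for i, t in enumerate(design.treatments)},
        C_true=C, sigma_block=sigma_block, sigma_bed_A=sigma_bed_A,
        sigma_bed_B=sigma_bed_B, noise_sd=noise_sd,
    )
    ds = simulate_experiment(design, [truth], seed=seed)
    return ds, truth


def flush_frame(ds):
    """Transformed (t', y') table of a one-flush dataset."""
    b = FlushBoundaries(boundary_days=[], config=SegmentationConfig())
    return split_flushes(ds.yield_table, b)


def nls_oracle(model):
    """Brute-force weighted NLS with treatment-specific (A, B) and shared C,
    multistarted over a coarse grid; independent of the SAEM code path."""
    from scipy.optimize import least_squares

    n_t = len(model.treatments)
    t, y, gi = model.t, model.y, model.bed_trt[model.bed_index]
    sw = np.sqrt(model.weights)

    def f(th):
        A, B, C = th[:n_t][gi], th[n_t:2 * n_t][gi], th[-1]
        return sw * (y - A * np.exp(-np.exp(B - C * t)))

    best = None
    for a0 in (0.5 * y.max(), 1.2 * y.max()):
        for c0 in (0.05, 0.1, 0.2):
            r = least_squares(f, x0=[a0] * n_t + [2.0] * n_t + [c0])
            if best is None or r.cost < best.cost:
                best = r
    return best.x
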