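"""Synthetic ground-truth cohorts for end-to-end pipeline testing.

Generates subjects x extinction blocks of two-region evoked responses
whose extrinsic connection strengths covary with trial number and
freezing, plus noisy single trials at a controlled SNR, a covariate
table and the generating parameter values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .neural_mass import (
    EvokedResponse,
    ModelVariant,
    SimulationError,
    SimulationGrid,
    build_model_space,
    compile_variant,
)

__all__ = [
    "CohortConfig",
    "BlockRecord",
    "CohortDataset",
    "freezing_trajectory",
    "generate_cohort",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth structure of one simulated cohort.

    ``effect_*`` values apply to the latent log strength of the extrinsic
    connections: either a scalar (applied to every connection parameter)
    or a mapping from parameter name (e.g. ``A_MCN_to_vlPAG``) to value.
    The latent strength for subject s, block b is

        theta_sb = effect_mean + effect_trial * (b - mean(b))
                   + effect_freeze * (freeze_sb - mean(freeze))
                   + subject_offset_s
    """

    n_subjects: int = 6
    n_blocks: int = 5
    trials_per_block: int = 7
    native_rate: float = 30_000.0
    effect_mean: float | dict = 0.0
    effect_trial: float | dict = 0.0
    effect_freeze: float | dict = 0.0
    subject_sd: float = 0.1
    noise_snr_db: float = 10.0
    freezing_start: float = 80.0
    freezing_end: float = 10.0
    freezing_noise_sd: float = 5.0
    noise_ar1: float = 0.0  # optional AR(1) coefficient for trial noise
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_blocks < 1 or self.trials_per_block < 1:
            raise CohortConfigError("counts must be >= 1")
        if self.native_rate <= 2 * 32.0:
            raise CohortConfigError("native rate must exceed twice the band upper edge")
        if np.isnan(self.noise_snr_db):
            raise CohortConfigError("noise_snr_db must be finite or +inf")
        if not -1.0 < self.noise_ar1 < 1.0:
            raise CohortConfigError("AR(1) coefficient must be in (-1, 1)")

    def effect(self, which: str, param: str) -> float:
        v = getattr(self, f"effect_{which}")
        if isinstance(v, dict):
            return float(v.get(param, 0.0))
        return float(v)


@dataclass
class BlockRecord:
    """One subject x block: noiseless ERPs, noisy trials, ground truth."""

    subject: int
    block: int
    freezing: float
    erp: dict[str, EvokedResponse]  # region -> noiseless ERP
    trials: dict[str, np.ndarray]  # region -> (n_trials, n_samples)
    true_theta: dict[str, float]  # generating latent parameters


@dataclass
class CohortDataset:
    config: CohortConfig
    variant_id: str
    records: list[BlockRecord]
    covariates: pd.DataFrame  # subject, block, freezing
    time_ms: np.ndarray

    def ground_truth_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"subject": r.subject, "block": r.block, "freezing": r.freezing}
            row.update(r.true_theta)
            rows.append(row)
        return pd.DataFrame(rows)

    def block_erps(self, subject: int, block: int) -> np.ndarray:
        """Trial-averaged waveforms (n_regions, n_samples), region order as generated."""
        r = next(x for x in self.records if x.subject == subject and x.block == block)
        return np.vstack([r.trials[k].mean(axis=0) for k in r.erp])


def freezing_trajectory(n_blocks: int, start_pct: float, end_pct: float,
                        noise_sd: float, seed: int) -> np.ndarray:
    """Declining per-block freezing percentages, clipped to [0, 100].

    The mean trajectory interpolates linearly from ``start_pct`` to
    ``end_pct``; zero-mean Gaussian noise of SD ``noise_sd`` is added.
    """
    if not (0 <= end_pct <= start_pct <= 100):
        raise CohortConfigError(
            f"freezing bounds must satisfy 0 <= end <= start <= 100, got "
            f"({start_pct}, {end_pct})")
    if n_blocks < 1:
        raise CohortConfigError("n_blocks must be >= 1")
    mean = np.linspace(start_pct, end_pct, n_blocks)
    rng = np.random.default_rng(seed)
    vals = mean + rng.normal(0.0, noise_sd, size=n_blocks) if noise_sd > 0 else mean
    return np.clip(vals, 0.0, 100.0)


def _trial_noise(rng, shape, sigma, ar1):
    eps = rng.normal(0.0, sigma, size=shape)
    if ar1 == 0.0:
        return eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    for t in range(1, shape[-1]):
        out[..., t] = ar1 * out[..., t - 1] + np.sqrt(1.0 - ar1**2) * eps[..., t]
    return out


def generate_cohort(config: CohortConfig,
                    variant: ModelVariant | None = None,
                    grid: SimulationGrid = SimulationGrid()) -> CohortDataset:
    """Simulate a full cohort under one model variant.

    Bitwise reproducible for a fixed seed.  Trial noise is additive
    Gaussian (optionally AR(1)) scaled so that the per-trial SNR --
    noiseless ERP power over noise power -- equals ``noise_snr_db``.
    """
    if variant is None:
        variant = build_model_space()[0]
    cv = compile_variant(variant, grid)
    extrinsic_params = [c.param for c in variant.extrinsic]
    rng = np.random.default_rng(config.seed)

    records = []
    cov_rows = []
    blocks = np.arange(1, config.n_blocks + 1, dtype=float)
    b_center = blocks - blocks.mean()

    # per-subject freezing trajectories and latent offsets
    freeze = np.stack([
        freezing_trajectory(config.n_blocks, config.freezing_start,
                            config.freezing_end, config.freezing_noise_sd,
                            int(rng.integers(0, 2**31)))
        for _ in range(config.n_subjects)
    ])
    f_center = freeze - freeze.mean()
    offsets = {p: rng.normal(0.0, config.subject_sd, size=config.n_subjects)
               for p in dict.fromkeys(extrinsic_params)}

    for s in range(1, config.n_subjects + 1):
        for bi, b in enumerate(blocks):
            theta = {}
            for p in dict.fromkeys(extrinsic_params):
                theta[p] = (config.effect("mean", p)
                            + config.effect("trial", p) * b_center[bi]
                            + config.effect("freeze", p) * f_center[s - 1, bi]
                            + offsets[p][s - 1])
            try:
                Y = cv.simulate(theta)
            except SimulationError as err:
                raise SimulationError(
                    f"subject {s} block {int(b)}: {err}; draw: {theta}") from err
            if not np.all(np.isfinite(Y)):
                raise SimulationError(
                    f"subject {s} block {int(b)}: non-finite waveform for draw {theta}")
            if np.isinf(config.noise_snr_db):
                trials_noise = np.zeros((len(cv.source_names),
                                         config.trials_per_block, Y.shape[1]))
            else:
                # noise scaled per region so each channel attains the target SNR
                sig_power = np.mean(Y**2, axis=1)
                sigma = np.sqrt(sig_power / 10.0 ** (config.noise_snr_db / 10.0))
                trials_noise = _trial_noise(
                    rng, (len(cv.source_names), config.trials_per_block, Y.shape[1]),
                    1.0, config.noise_ar1) * sigma[:, None, None]
            erp = {nm: EvokedResponse(region=nm, time_ms=grid.output_times.copy(),
                                      amplitude=Y[i],
                                      n_trials=config.trials_per_block)
                   for i, nm in enumerate(cv.source_names)}
            trials = {nm: Y[i][None, :] + trials_noise[i]
                      for i, nm in enumerate(cv.source_names)}
            records.append(BlockRecord(subject=s, block=int(b),
                                       freezing=float(freeze[s - 1, bi]),
                                       erp=erp, trials=trials, true_theta=theta))
            cov_rows.append({"subject": s, "block": int(b),
                             "freezing": float(freeze[s - 1, bi])})
    return CohortDataset(config=config, variant_id=variant.id, records=records,
                        covariates=pd.DataFrame(cov_rows),
                        time_ms=grid.output_times.copy())
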