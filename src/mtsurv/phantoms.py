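"""Synthetic tumor-phantom cohorts with proportional-hazards outcomes.

Each phantom is a noisy background volume containing one ellipsoidal
"tumor" of elevated mean intensity (CT-like, in Hounsfield-unit scale so
the standard clip/normalize preprocessing applies); the binary mask marks
the ellipsoid.  The single prognostic factor is tumor size: the true
log-hazard is

    gamma_i = beta * (log V_i - mu_logV) / sigma_logV,

with V_i the analytic ellipsoid volume 4/3*pi*a*b*c and the standardization
moments computed in closed form from the uniform semi-axis distribution, so
patients are generated independently and exchangeably.  Event times are
exponential with rate ``baseline_rate * exp(gamma)``, censoring times are
independent exponentials at ``censoring_rate``, and follow-up is truncated
at 120 months (censored at truncation).  An optional second, PET-like
channel carries tumor intensity proportional to the true log-hazard.

Ground truth (log-hazard, volumes, latent event/censoring times) is
retained for recovery tests: no trained model can discriminate better than
the true log-hazard itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import VolumeSample, save_cohort
from .survival import SurvivalRecord

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "tiny_phantom_spec",
    "generate_phantom",
    "generate_cohort",
    "generate_outcomes",
    "oracle_cindex",
    "write_cohort",
]

HORIZON_MONTHS = 120.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of a synthetic cohort."""

    cohort_size: int = 200
    volume_shape: tuple = (72, 88, 88)
    channels: int = 1
    radius_range: tuple = (4.0, 14.0)
    background_hu: float = -80.0
    contrast_hu: float = 140.0
    noise_sd: float = 20.0
    true_effect: float = 1.5
    baseline_rate: float = 0.010
    censoring_rate: float = 0.008
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid radius range ({lo}, {hi})")
        if any(2 * hi >= s for s in self.volume_shape):
            raise ValueError(
                f"ellipsoid radii up to {hi} cannot fit inside volume {self.volume_shape}"
            )
        if self.baseline_rate <= 0 or self.censoring_rate < 0:
            raise ValueError("rates must be positive (censoring may be zero)")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 or 2")


def tiny_phantom_spec(**overrides) -> PhantomSpec:
    """Desk-scale conditions matched to the 16^3 tiny network preset."""
    defaults = dict(volume_shape=(24, 24, 24), radius_range=(1.5, 5.0))
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@dataclass(frozen=True)
class PhantomTruth:
    """Per-patient generative ground truth."""

    patient_id: str
    log_hazard: float
    analytic_volume: float
    voxel_volume: int
    semi_axes: tuple
    event_time: float = np.nan
    censor_time: float = np.nan


def _log_uniform_moments(lo: float, hi: float) -> tuple[float, float]:
    """Mean and variance of ln(U) for U ~ Uniform(lo, hi), closed form."""
    width = hi - lo
    m1 = (hi * np.log(hi) - lo * np.log(lo)) / width - 1.0

    def antiderivative(x):
        lx = np.log(x)
        return x * (lx**2 - 2 * lx + 2)

    m2 = (antiderivative(hi) - antiderivative(lo)) / width
    return m1, m2 - m1**2


def log_volume_moments(spec: PhantomSpec) -> tuple[float, float]:
    """Mean and SD of the log analytic ellipsoid volume under the spec."""
    m1, v1 = _log_uniform_moments(*spec.radius_range)
    mean = float(np.log(4.0 / 3.0 * np.pi) + 3.0 * m1)
    sd = float(np.sqrt(3.0 * v1))
    return mean, sd


def true_log_hazard(spec: PhantomSpec, semi_axes) -> float:
    mu, sd = log_volume_moments(spec)
    volume = 4.0 / 3.0 * np.pi * float(np.prod(semi_axes))
    return float(spec.true_effect * (np.log(volume) - mu) / sd)


def generate_phantom(spec: PhantomSpec, index: int) -> tuple[VolumeSample, PhantomTruth]:
    """Generate one phantom volume; reproducible from (spec.seed, index).

    The outcome record is attached later by :func:`generate_outcomes`; the
    returned sample carries a placeholder record (time 0, censored).
    """
    rng = np.random.default_rng((spec.seed, index))
    shape = spec.volume_shape
    semi_axes = tuple(rng.uniform(*spec.radius_range, size=3))
    margin = [int(np.ceil(r)) + 1 for r in semi_axes]
    center = [rng.uniform(margin[a], shape[a] - margin[a]) for a in range(3)]
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    inside = (
        sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, semi_axes)) <= 1.0
    )
    mask = inside.astype(np.uint8)

    gamma = true_log_hazard(spec, semi_axes)
    ct = np.full(shape, spec.background_hu, dtype=np.float32)
    ct[inside] += spec.contrast_hu
    if spec.noise_sd > 0:
        ct += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    channels = [ct]
    if spec.channels == 2:
        # PET-like channel: tumor uptake proportional to the true log-hazard
        pet = np.zeros(shape, dtype=np.float32)
        pet[inside] = 3.0 + 1.5 * gamma
        if spec.noise_sd > 0:
            pet += rng.normal(0.0, 0.25, size=shape).astype(np.float32)
        channels.append(pet)

    pid = f"P{index:04d}"
    truth = PhantomTruth(
        patient_id=pid,
        log_hazard=gamma,
        analytic_volume=4.0 / 3.0 * np.pi * float(np.prod(semi_axes)),
        voxel_volume=int(mask.sum()),
        semi_axes=semi_axes,
    )
    sample = VolumeSample(
        np.stack(channels), mask, SurvivalRecord(0.0, 0, pid), patient_id=pid
    )
    return sample, truth


def generate_outcomes(truths, spec: PhantomSpec) -> list[SurvivalRecord]:
    """Draw censored outcomes from the proportional-hazards mechanism.

    Event times are exponential with rate ``baseline_rate * exp(gamma)``;
    independent exponential censoring competes at ``censoring_rate``;
    follow-up is truncated (censored) at 120 months.  Returns records in
    truth order and stores the latent times back onto the truth objects.
    """
    rng = np.random.default_rng((spec.seed, 0xC0F))
    records = []
    updated = []
    for truth in truths:
        rate = spec.baseline_rate * np.exp(truth.log_hazard)
        event_time = float(rng.exponential(1.0 / rate))
        censor_time = (
            float(rng.exponential(1.0 / spec.censoring_rate))
            if spec.censoring_rate > 0
            else np.inf
        )
        time = min(event_time, censor_time, HORIZON_MONTHS)
        event = int(event_time <= censor_time and event_time < HORIZON_MONTHS)
        records.append(SurvivalRecord(time, event, truth.patient_id))
        updated.append(
            PhantomTruth(
                truth.patient_id,
                truth.log_hazard,
                truth.analytic_volume,
                truth.voxel_volume,
                truth.semi_axes,
                event_time,
                censor_time,
            )
        )
    truths[:] = updated
    return records


def generate_cohort(spec: PhantomSpec) -> tuple[list[VolumeSample], list[PhantomTruth]]:
    """Generate the full cohort with outcomes attached to each sample."""
    pairs = [generate_phantom(spec, i) for i in range(spec.cohort_size)]
    samples = [s for s, _ in pairs]
    truths = [t for _, t in pairs]
    records = generate_outcomes(truths, spec)
    for sample, record in zip(samples, records):
        sample.record = record
    return samples, truths


def oracle_cindex(truths, records) -> float:
    """Concordance of the true log-hazard against the simulated outcomes.

    Hazard-oriented predictions: values well below 0.5 indicate that large
    true hazards align with short event times; this is the discrimination
    ceiling for any model trained on the cohort.
    """
    from .evaluation import concordance_index

    preds = np.array([t.log_hazard for t in truths])
    return concordance_index(preds, records, orientation="hazard").c_index


def truth_table(truths) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in truths],
            "log_hazard": [t.log_hazard for t in truths],
            "analytic_volume": [t.analytic_volume for t in truths],
            "voxel_volume": [t.voxel_volume for t in truths],
            "event_time": [t.event_time for t in truths],
            "censor_time": [t.censor_time for t in truths],
        }
    )


def write_cohort(spec: PhantomSpec, directory) -> Path:
    """Materialize a cohort in the on-disk layout the pipeline consumes."""
    directory = Path(directory)
    samples, truths = generate_cohort(spec)
    manifest = save_cohort(samples, directory)
    truth_table(truths).to_csv(directory / "truth.csv", index=False)
    return manifest
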