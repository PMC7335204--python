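"""Two-cohort synthetic resting-state datasets with known ground truth.

No raw data are deposited for the study design this package analyzes, so
every downstream stage is exercised on synthetic subjects: multivariate
Gaussian ROI time series drawn from a planted block-modular covariance,
motion traces with smooth drift plus spike artifacts, autocorrelated
nuisance signals partially mixed into the ROI signals, and questionnaire
scores drawn from truncated Gaussians whose per-group locations mirror
the published cohort descriptives (a mild Japanese cohort, "sendai", and
a more severe Swedish cohort, "gothenburg").

All randomness flows from the single seed in the config; cohorts are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import CensorMask, MotionTrace, RoiTimeSeries, SubjectRecord

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "plant_covariance",
    "generate_subject",
    "generate_cohort",
    "sendai_config",
    "gothenburg_config",
    "simulate_measure_records",
]

# Instrument score ranges (used to truncate the Gaussian draws).
INSTRUMENT_RANGES = {
    "ibs_sss_colonic": (0.0, 500.0),
    "ibs_sss_extracolonic": (0.0, 500.0),
    "vsi": (0.0, 75.0),
    "stai_t": (20.0, 80.0),
    "sds": (20.0, 80.0),
    "hads_total": (0.0, 42.0),
    "age": (18.0, 65.0),
}


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``module_sizes``, ``within_r`` and ``between_r`` plant the modular
    covariance; ``group_effect`` shifts the between-module correlation of
    the patient group (a loss of segregation; 0 reproduces the null
    regime).  ``questionnaire_params`` maps instrument -> group ->
    (location, scale) of a Gaussian truncated to the instrument range.
    """

    n_hc: int
    n_ibs: int
    cohort: str = "sendai"
    n_nodes: int = 45
    n_volumes: int = 250
    analyze_volumes: Optional[int] = None  # truncate runs to this many volumes
    tr: float = 1.8
    module_sizes: tuple[int, ...] = (15, 15, 15)
    within_r: float = 0.4
    between_r: float = 0.1
    group_effect: float = 0.0
    motion_spike_rate: float = 0.02
    motion_spike_scale: float = 1.5  # mm
    drift_amplitude_mm: float = 0.2
    drift_amplitude_rad: float = 0.002
    nuisance_mix: float = 0.3
    questionnaire_params: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    sex_m_fraction: dict[str, float] = field(default_factory=lambda: {"HC": 0.5, "IBS": 0.5})
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum {sum(self.module_sizes)} != n_nodes {self.n_nodes}"
            )
        if not 0 <= self.between_r < self.within_r < 1:
            raise ValueError("need 0 <= between_r < within_r < 1")
        ibs_between = self.between_r + self.group_effect
        if not 0 <= ibs_between < self.within_r:
            raise ValueError("IBS between-module correlation must stay in [0, within_r)")
        if self.n_hc < 0 or self.n_ibs < 0 or self.n_hc + self.n_ibs == 0:
            raise ValueError("cohort must contain at least one subject")
        if not 0 <= self.motion_spike_rate <= 1:
            raise ValueError("motion_spike_rate must be a probability")

    def covariance_for(self, group: str) -> np.ndarray:
        between = self.between_r + (self.group_effect if group == "IBS" else 0.0)
        return plant_covariance(self.module_sizes, self.within_r, between)


@dataclass
class SyntheticSubject:
    """One simulated subject with full ground truth attached."""

    roi_series: RoiTimeSeries
    motion: MotionTrace
    nuisance: np.ndarray  # (T, 3): WM, CSF, global
    record: SubjectRecord
    true_partition: np.ndarray  # module id per node
    true_covariance: np.ndarray


def plant_covariance(
    module_sizes: tuple[int, ...], within_r: float, between_r: float = 0.0
) -> np.ndarray:
    """Unit-diagonal block covariance: ``within_r`` inside modules,
    ``between_r`` across modules.

    Positive definite whenever 0 <= between_r < within_r < 1 (checked
    numerically; violations are rejected with the offending eigenvalue).
    """
    n = sum(module_sizes)
    cov = np.full((n, n), float(between_r))
    start = 0
    for size in module_sizes:
        cov[start : start + size, start : start + size] = within_r
        start += size
    np.fill_diagonal(cov, 1.0)
    eigmin = float(np.linalg.eigvalsh(cov)[0])
    if eigmin <= 0:
        raise ValueError(
            f"planted covariance is not positive definite (smallest eigenvalue {eigmin:.4g})"
        )
    return cov


def _module_labels(module_sizes: tuple[int, ...]) -> np.ndarray:
    return np.repeat(np.arange(len(module_sizes)), module_sizes)


def _truncnorm_draw(
    loc: float, scale: float, bounds: tuple[float, float], rng: np.random.Generator
) -> float:
    lo, hi = bounds
    if scale <= 0:
        return float(np.clip(loc, lo, hi))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))


def _motion_trace(config: CohortConfig, rng: np.random.Generator) -> MotionTrace:
    t = np.arange(config.n_volumes)
    trans = np.zeros((config.n_volumes, 3))
    rot = np.zeros((config.n_volumes, 3))
    for j in range(3):
        phase_t, phase_r = rng.uniform(0, 2 * np.pi, size=2)
        ncyc_t, ncyc_r = rng.uniform(0.5, 2.0, size=2)
        trans[:, j] = config.drift_amplitude_mm * np.sin(
            2 * np.pi * ncyc_t * t / config.n_volumes + phase_t
        )
        rot[:, j] = config.drift_amplitude_rad * np.sin(
            2 * np.pi * ncyc_r * t / config.n_volumes + phase_r
        )
    spikes = rng.random(config.n_volumes) < config.motion_spike_rate
    spikes[0] = False  # keep the reference volume clean
    for idx in np.nonzero(spikes)[0]:
        axis = rng.integers(3)
        sign = rng.choice([-1.0, 1.0])
        trans[idx, axis] += sign * config.motion_spike_scale
    return MotionTrace(trans, rot)


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(n) * np.sqrt(1 - phi**2)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    for t in range(1, n):
        out[t] = phi * out[t - 1] + innov[t]
    return out


def generate_subject(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
) -> SyntheticSubject:
    """Draw one subject: ROI series from the planted covariance, motion,
    nuisance signals mixed into the ROI data, and questionnaire scores."""
    if group not in ("HC", "IBS"):
        raise ValueError("group must be 'HC' or 'IBS'")
    cov = config.covariance_for(group)
    chol = np.linalg.cholesky(cov)
    series = rng.standard_normal((config.n_volumes, config.n_nodes)) @ chol.T

    nuisance = np.column_stack([_ar1(config.n_volumes, 0.9, rng) for _ in range(3)])
    wm, csf, glob = nuisance.T
    contamination = config.nuisance_mix * (glob + 0.5 * wm + 0.5 * csf)
    series = series + contamination[:, None]

    motion = _motion_trace(config, rng)

    scores: dict[str, float] = {}
    for instrument, per_group in config.questionnaire_params.items():
        loc, scale = per_group[group]
        bounds = INSTRUMENT_RANGES.get(instrument, (-np.inf, np.inf))
        scores[instrument] = _truncnorm_draw(loc, scale, bounds, rng)
    scores["sex_m"] = float(rng.random() < config.sex_m_fraction.get(group, 0.5))

    record = SubjectRecord(subject_id=subject_id, group=group, cohort=config.cohort, scores=scores)
    ts = RoiTimeSeries(series, config.tr, mask=CensorMask.clean(config.n_volumes))
    return SyntheticSubject(
        roi_series=ts,
        motion=motion,
        nuisance=nuisance,
        record=record,
        true_partition=_module_labels(config.module_sizes),
        true_covariance=cov,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate all subjects of a cohort plus a participants manifest.

    HC subjects come first, then IBS; each subject consumes an independent
    child stream of the config seed, so the cohort is reproducible as a
    whole and per subject.
    """
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_hc + config.n_ibs)
    subjects: list[SyntheticSubject] = []
    rows = []
    groups = ["HC"] * config.n_hc + ["IBS"] * config.n_ibs
    for i, (group, child) in enumerate(zip(groups, children)):
        sid = f"sub-{i:03d}"
        subject = generate_subject(config, group, np.random.default_rng(child), sid)
        subjects.append(subject)
        row = {"subject_id": sid, "group": group, "cohort": config.cohort}
        row.update(subject.record.scores)
        rows.append(row)
    manifest = pd.DataFrame(rows).set_index("subject_id")
    return subjects, manifest


def sendai_config(**overrides) -> CohortConfig:
    """Cohort emulating the milder 29 HC / 30 IBS sample (TR 1.8 s,
    250 volumes): large group separation on GI symptom severity and
    GI-specific anxiety, none on trait anxiety or depressive symptoms."""
    params = {
        "ibs_sss_colonic": {"HC": (41.0, 50.0), "IBS": (179.5, 47.0)},
        "stai_t": {"HC": (36.0, 5.6), "IBS": (38.5, 10.0)},
        "sds": {"HC": (35.5, 4.1), "IBS": (35.5, 9.3)},
        "vsi": {"HC": (1.0, 3.7), "IBS": (24.5, 14.5)},
        "age": {"HC": (22.0, 2.8), "IBS": (22.4, 3.6)},
    }
    defaults = dict(
        n_hc=29,
        n_ibs=30,
        cohort="sendai",
        tr=1.8,
        n_volumes=250,
        questionnaire_params=params,
        sex_m_fraction={"HC": 15 / 29, "IBS": 13 / 30},
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def gothenburg_config(**overrides) -> CohortConfig:
    """Cohort emulating the more severe 29 HC / 62 IBS sample (TR 2.0 s,
    300 acquired volumes of which the first 250 are analyzed): group
    separation on every symptom instrument including psychological
    distress (HADS total)."""
    params = {
        "ibs_sss_colonic": {"HC": (12.0, 18.5), "IBS": (295.0, 119.0)},
        "ibs_sss_extracolonic": {"HC": (33.5, 27.4), "IBS": (155.25, 90.8)},
        "hads_total": {"HC": (5.0, 3.0), "IBS": (14.0, 6.0)},
        "vsi": {"HC": (1.0, 1.5), "IBS": (39.0, 20.0)},
        "age": {"HC": (32.1, 8.0), "IBS": (32.9, 9.6)},
    }
    defaults = dict(
        n_hc=29,
        n_ibs=62,
        cohort="gothenburg",
        tr=2.0,
        n_volumes=300,
        analyze_volumes=250,
        questionnaire_params=params,
        sex_m_fraction={"HC": 10 / 29, "IBS": 17 / 62},
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def simulate_measure_records(
    n_hc: int,
    n_ibs: int,
    rng: np.random.Generator,
    slope_hc: float = 0.0,
    slope_ibs: float = 0.0,
    group_shift: float = 0.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Subject-level records of one normalized measure and one covariate.

    Used for statistical calibration and power studies at the level the
    group-statistics layer consumes: covariate ~ N(0, 1) per subject,
    measure = group shift + per-group slope * covariate + N(0, noise_sd^2).
    Slopes of zero give the global-null regime.
    """
    n = n_hc + n_ibs
    group = np.array(["HC"] * n_hc + ["IBS"] * n_ibs)
    z = rng.standard_normal(n)
    slope = np.where(group == "HC", slope_hc, slope_ibs)
    shift = np.where(group == "HC", 0.0, group_shift)
    y = shift + slope * z + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"group": group, "covariate": z, "measure": y})
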