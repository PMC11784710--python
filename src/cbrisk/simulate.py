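"""Synthetic cohort generator.

Emulates the statistical structure the pipeline consumes, not physiology:

* per-subject AR(1) heart-rate and respiratory-rate series around
  subject-level baselines (autocorrelated noise keeps K-means clusters
  temporally contiguous, which the pattern taxonomy presupposes);
* a transient ventilatory depression at the post-hyperoxia minutes (the
  carotid-body response), with a *larger per-minute jitter* in the
  prediabetes group — the feature that drives its higher cluster
  variability;
* a mild heart-rate bump after the meal minute;
* glucose trajectories whose group means diverge inside the severity-level
  window (minutes 34-55 by default): the prediabetes postprandial rise is
  larger and decays more slowly.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, Group, StimulusProtocol, SubjectRecord

__all__ = ["GeneratorParams", "generate_cohort"]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort generator (units in field comments)."""

    n_control: int = 25
    n_prediabetes: int = 8
    seed: int = 42

    # subject-level baselines: (mean, sd) across subjects
    hr_baseline: tuple[float, float] = (70.0, 8.0)  # beats/min
    rr_baseline_control: tuple[float, float] = (17.1, 1.5)  # breaths/min
    rr_baseline_prediabetes: tuple[float, float] = (15.5, 1.5)

    # minute-to-minute AR(1) noise
    ar1_rho: float = 0.6
    hr_noise_sd: float = 1.5  # innovation sd, beats/min
    rr_noise_sd: float = 0.5  # innovation sd, breaths/min

    # post-hyperoxia ventilatory depression at the window minutes:
    # per-minute draws N(mean, sd) subtracted from RR; the prediabetes sd is
    # deliberately larger (deregulated chemosensitivity -> jittery response)
    oxy_dip_mean_control: float = 1.5
    oxy_dip_sd_control: float = 0.4
    oxy_dip_mean_prediabetes: float = 2.5
    oxy_dip_sd_prediabetes: float = 2.0
    oxy_hr_scale: float = 3.0  # HR window perturbation = scale x RR-dip draws

    meal_hr_bump: float = 4.0  # beats/min reached after the meal minute

    # glucose: (mean, sd) subject baseline and postprandial bump height
    glucose_baseline_control: tuple[float, float] = (90.0, 5.0)
    glucose_baseline_prediabetes: tuple[float, float] = (105.0, 10.0)
    postprandial_rise_control: float = 20.0  # mg/dL peak above baseline
    postprandial_rise_prediabetes: float = 45.0
    glucose_decay_control: float = 8.0  # minutes; larger = slower return
    glucose_decay_prediabetes: float = 16.0
    glucose_noise_sd: float = 1.5

    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_prediabetes < 0:
            raise ValueError("subject counts must be non-negative")
        for name in (
            "hr_noise_sd",
            "rr_noise_sd",
            "oxy_dip_sd_control",
            "oxy_dip_sd_prediabetes",
            "glucose_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _ar1(rng: np.ndarray, n: int, mu: float, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of length n around mu."""
    x = np.empty(n)
    stat_sd = sd / np.sqrt(1.0 - rho**2) if abs(rho) < 1 else sd
    x[0] = mu + rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = mu + rho * (x[t - 1] - mu) + eps[t - 1]
    return x


def _meal_ramp(minutes: np.ndarray, meal_minute: int, height: float) -> np.ndarray:
    """Smooth rise from 0 to ``height`` over ~5 minutes after the meal."""
    rel = np.clip((minutes - meal_minute) / 5.0, 0.0, 1.0)
    return height * rel


def _glucose_bump(
    minutes: np.ndarray, meal_minute: int, height: float, decay: float
) -> np.ndarray:
    """Gamma-shaped postprandial excursion starting at the meal minute."""
    u = np.clip((minutes - meal_minute) / decay, 0.0, None)
    return height * u * np.exp(1.0 - u)


def _simulate_subject(
    rng,
    subject_id: str,
    group: Group,
    params: GeneratorParams,
) -> SubjectRecord:
    p = params
    proto = p.protocol
    minutes = proto.minutes
    T = proto.total_minutes
    win = proto.window_minutes - 1  # grid indices of the post-oxygen minutes

    if group is Group.CONTROL:
        rr_mu = rng.normal(*p.rr_baseline_control)
        dip_mean, dip_sd = p.oxy_dip_mean_control, p.oxy_dip_sd_control
        g_base = rng.normal(*p.glucose_baseline_control)
        g_rise, g_decay = p.postprandial_rise_control, p.glucose_decay_control
    else:
        rr_mu = rng.normal(*p.rr_baseline_prediabetes)
        dip_mean, dip_sd = p.oxy_dip_mean_prediabetes, p.oxy_dip_sd_prediabetes
        g_base = rng.normal(*p.glucose_baseline_prediabetes)
        g_rise, g_decay = p.postprandial_rise_prediabetes, p.glucose_decay_prediabetes

    hr_mu = rng.normal(*p.hr_baseline)
    hr = _ar1(rng, T, hr_mu, p.ar1_rho, p.hr_noise_sd)
    rr = _ar1(rng, T, rr_mu, p.ar1_rho, p.rr_noise_sd)

    # hyperoxia: per-minute ventilatory depression, mirrored (scaled) in HR
    dips = rng.normal(dip_mean, dip_sd, size=win.size)
    rr[win] -= dips
    hr[win] -= p.oxy_hr_scale * rng.normal(dip_mean, dip_sd, size=win.size)

    hr += _meal_ramp(minutes, proto.meal_minute, p.meal_hr_bump)

    glucose = (
        g_base
        + _glucose_bump(minutes, proto.meal_minute, g_rise, g_decay)
        + rng.normal(0.0, p.glucose_noise_sd, size=T)
    )

    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        minutes=minutes,
        hr=np.clip(hr, 40.0, None),
        rr=np.clip(rr, 5.0, None),
        glucose=np.clip(glucose, 0.0, None),
    )


def generate_cohort(params: GeneratorParams = GeneratorParams()) -> Cohort:
    """Generate a reproducible synthetic cohort under the study protocol."""
    rng = np.random.default_rng(params.seed)
    subjects = []
    for i in range(params.n_prediabetes):
        subjects.append(
            _simulate_subject(
                rng, f"sim-pre-{i + 1:03d}", Group.PREDIABETES, params
            )
        )
    for i in range(params.n_control):
        subjects.append(
            _simulate_subject(rng, f"sim-ctl-{i + 1:03d}", Group.CONTROL, params)
        )
    return Cohort(subjects=tuple(subjects), protocol=params.protocol)
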