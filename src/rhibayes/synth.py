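"""Seeded synthetic cohorts with the statistical structure the analyses assume.

The generators emulate the deposited per-subject tables of the two
experiments so the full analysis pipeline is exercisable without any
download.  Experiment-1 cohorts have Gaussian localization noise around a
true hand position with a midline-ward bias, group-dependent injected drift,
and ordinal ownership ratings coupled to drift through a discretized latent
Gaussian.  Experiment-2 cohorts have tonic skin-conductance traces with
event-locked rise-and-decay responses whose amplitudes differ by group and
couple to the ownership rating.

Default magnitudes mirror the empirical report the pipeline targets: a
baseline localization bias of 31.5 mm toward the midline with a 13 mm
within-subject SD, group drift means giving one-sample effect sizes of
roughly 1.0 / 0.6 / 0.5 / 0.25 (sync / async / no-stroke / no-hand), and
ownership-drift correlations in the 0.3-0.45 range.  Everything is
configurable and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import (
    EXP1_GROUPS,
    EXP2_GROUPS,
    Exp1Record,
    Exp2Record,
)

__all__ = [
    "Exp1GenConfig",
    "Exp2GenConfig",
    "generate_exp1",
    "generate_exp2",
    "write_exp1_csv",
    "write_exp2_csv",
]


@dataclass(frozen=True)
class Exp1GenConfig:
    n_per_group: int = 21
    n_localizations: int = 40
    true_hand_position: float = 320.0      # mm from midline
    baseline_bias: float = 31.5            # mm toward midline
    within_subject_sd: float = 13.0        # mm, localization noise
    between_subject_sd: float = 15.0       # mm, spread of subject means
    # injected mean drift per group, mm toward the rubber hand
    drift_means: dict = field(
        default_factory=lambda: {
            "sync": 10.0, "async": 6.0, "no_stroke": 5.0, "no_hand": 2.5
        }
    )
    drift_sd: float = 10.0                 # mm, between-subject drift spread
    # ownership latent = intercept(group) + slope * drift + N(0, rating_noise)
    ownership_intercepts: dict = field(
        default_factory=lambda: {
            "sync": 1.1, "async": 1.1, "no_stroke": 1.1, "no_hand": -2.0
        }
    )
    ownership_slope: float = 0.06          # per mm of drift
    rating_noise: float = 1.5

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("within_subject_sd", "between_subject_sd", "drift_sd", "rating_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for g in self.drift_means:
            if g not in EXP1_GROUPS:
                raise ValueError(f"unknown group {g!r} in drift_means")


def _discretize_rating(latent: np.ndarray) -> np.ndarray:
    """Cut a latent Gaussian at half-integer thresholds into -3..3."""
    return np.clip(np.rint(latent), -3, 3).astype(int)


def generate_exp1(
    config: Exp1GenConfig = Exp1GenConfig(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Exp1Record]:
    """Generate one Experiment-1 cohort (deterministic per seed).

    Per subject: latent localization mean = true position - bias +
    between-subject noise; ``n_localizations`` pre-test draws around it; the
    same number of post-test draws shifted by the subject's drift (group mean
    plus subject-level noise); pre- and post-test ownership ratings
    discretized from a latent Gaussian coupled to the subject's drift.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    records = []
    for group in EXP1_GROUPS:
        if group not in config.drift_means:
            continue
        for i in range(config.n_per_group):
            subj_mean = (
                config.true_hand_position
                - config.baseline_bias
                + rng.normal(0.0, config.between_subject_sd)
            )
            drift = config.drift_means[group] + rng.normal(0.0, config.drift_sd)
            pre = rng.normal(subj_mean, config.within_subject_sd, config.n_localizations)
            post = rng.normal(
                subj_mean + drift, config.within_subject_sd, config.n_localizations
            )
            base = config.ownership_intercepts.get(group, 0.0)
            lat_pre = base + config.ownership_slope * drift + rng.normal(0, config.rating_noise)
            lat_post = base + config.ownership_slope * drift + rng.normal(0, config.rating_noise)
            rec = Exp1Record(
                subject=f"{group}_{i+1:02d}",
                group=group,
                pre=pre,
                post=post,
                pre_ownership=int(_discretize_rating(np.asarray(lat_pre))),
                post_ownership=int(_discretize_rating(np.asarray(lat_post))),
                true_hand_position=config.true_hand_position,
            )
            rec.validate()
            records.append(rec)
    return records


def write_exp1_csv(records: Sequence[Exp1Record], path, config=None) -> None:
    """Write a cohort in the wide one-row-per-subject dialect that
    :func:`rhibayes.analysis.load_exp1` reads, plus a JSON sidecar with the
    generative parameters when a config is given."""
    rows = []
    for r in records:
        row = {
            "subject": r.subject,
            "group": r.group,
            "pre_ownership": r.pre_ownership,
            "post_ownership": r.post_ownership,
        }
        if r.true_hand_position is not None:
            row["true_hand_position_mm"] = r.true_hand_position
        row.update({f"pre_{i+1}": v for i, v in enumerate(np.asarray(r.pre))})
        row.update({f"post_{i+1}": v for i, v in enumerate(np.asarray(r.post))})
        rows.append(row)
    # %.17g keeps float64 values exact through the CSV round trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    if config is not None:
        _write_sidecar(Path(path).with_suffix(".params.json"), config)


# ---------------------------------------------------------------------------
# experiment 2
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Exp2GenConfig:
    n_per_group: int = 17
    duration_s: float = 120.0
    sampling_hz: float = 10.0              # fixed by the recording protocol
    tonic_level: float = 8.0               # microsiemens
    tonic_drift_amplitude: float = 0.1     # slow sinusoidal wander, uS
    tonic_drift_period_s: float = 90.0
    noise_sd: float = 0.02                 # per-sample measurement noise, uS
    event_times: dict = field(
        default_factory=lambda: {"eye_opening": 30.0, "threat": 90.0}
    )
    # (mean, sd) of the event response amplitude per group, uS
    amp_eye: dict = field(
        default_factory=lambda: {
            "plausible_arm": (0.9, 0.3), "hanging_arm": (0.25, 0.15),
            "no_arm": (0.25, 0.15),
        }
    )
    threat_scale: float = 0.85             # threat amplitude relative to eye-opening
    rise_s: float = 0.5                    # linear rise of the response bump
    decay_tau_s: float = 2.0               # exponential decay constant
    onset_latency_s: float = 1.2           # response onset after the event
    # ownership latent = group mean + coupling * standardized amplitude + noise
    ownership_means: dict = field(
        default_factory=lambda: {"plausible_arm": 1.8, "hanging_arm": -2.8}
    )
    ownership_coupling: float = 1.0
    ownership_noise: float = 0.8

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.sampling_hz != 10.0:
            raise ValueError("sampling rate is fixed at 10 Hz by the protocol")
        for name, ev in self.event_times.items():
            if not (0.0 <= ev and ev + 5.0 <= self.duration_s):
                raise ValueError(
                    f"event {name!r} at {ev}s leaves no 5 s response window "
                    f"within the {self.duration_s}s trace"
                )
        if self.noise_sd <= 0 or self.ownership_noise <= 0:
            raise ValueError("noise SDs must be > 0")


def _bump(t: np.ndarray, onset: float, amp: float, rise: float, tau: float) -> np.ndarray:
    """Event-related conductance bump: linear rise over ``rise`` s then
    exponential decay with constant ``tau``.  Shape is irrelevant to the
    max-min statistic beyond its amplitude."""
    dt = t - onset
    out = np.zeros_like(t)
    rising = (dt >= 0) & (dt < rise)
    out[rising] = amp * dt[rising] / rise
    decaying = dt >= rise
    out[decaying] = amp * np.exp(-(dt[decaying] - rise) / tau)
    return out


def generate_exp2(
    config: Exp2GenConfig = Exp2GenConfig(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Exp2Record]:
    """Generate one Experiment-2 cohort (deterministic per seed)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(config.duration_s * config.sampling_hz)) + 1
    t = np.arange(n) / config.sampling_hz
    records = []
    for group in EXP2_GROUPS:
        mu_eye, sd_eye = config.amp_eye[group]
        for i in range(config.n_per_group):
            phase = rng.uniform(0, 2 * np.pi)
            trace = (
                config.tonic_level
                + rng.normal(0.0, 0.5)      # subject-level tonic offset
                + config.tonic_drift_amplitude
                * np.sin(2 * np.pi * t / config.tonic_drift_period_s + phase)
                + rng.normal(0.0, config.noise_sd, n)
            )
            amp_eye = max(0.0, rng.normal(mu_eye, sd_eye))
            amp_threat = max(0.0, config.threat_scale * rng.normal(mu_eye, sd_eye))
            trace += _bump(
                t, config.event_times["eye_opening"] + config.onset_latency_s,
                amp_eye, config.rise_s, config.decay_tau_s,
            )
            trace += _bump(
                t, config.event_times["threat"] + config.onset_latency_s,
                amp_threat, config.rise_s, config.decay_tau_s,
            )
            ownership = None
            if group in config.ownership_means:
                latent = (
                    config.ownership_means[group]
                    + config.ownership_coupling * (amp_eye - mu_eye) / max(sd_eye, 1e-12)
                    + rng.normal(0.0, config.ownership_noise)
                )
                ownership = int(_discretize_rating(np.asarray(latent)))
            rec = Exp2Record(
                subject=f"{group}_{i+1:02d}",
                group=group,
                times=t,
                conductance=trace,
                event_times=dict(config.event_times),
                ownership=ownership,
            )
            rec.validate()
            records.append(rec)
    return records


def write_exp2_csv(records: Sequence[Exp2Record], out_dir, config=None) -> None:
    """Write a cohort as ``subjects.csv`` plus one trace CSV per subject under
    ``traces/``, the dialect :func:`rhibayes.analysis.load_exp2` reads."""
    out_dir = Path(out_dir)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        trace_file = f"traces/{r.subject}.csv"
        pd.DataFrame(
            {"time_s": np.asarray(r.times), "conductance_uS": np.asarray(r.conductance)}
        ).to_csv(out_dir / trace_file, index=False, float_format="%.17g")
        rows.append(
            {
                "subject": r.subject,
                "group": r.group,
                "trace_file": trace_file,
                "eye_opening_s": r.event_times["eye_opening"],
                "threat_s": r.event_times["threat"],
                "ownership": r.ownership,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "subjects.csv", index=False)
    if config is not None:
        _write_sidecar(out_dir / "subjects.params.json", config)


def _write_sidecar(path: Path, config) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
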