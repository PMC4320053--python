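"""Seeded Monte Carlo simulation of the rubber hand illusion model.

Three stimulation conditions are simulated:

``sync``
    brush strokes on the rubber and real hand coincide (temporal offset 0),
``async``
    strokes are delayed between the hands (default offset 750 ms, the
    midpoint of the 0.5–1 s range typically used),
``no_stroke``
    no strokes at all — the temporal dimension is removed from the model and
    the inference runs on the spatial cues alone.

On each trial noisy cues are drawn around the true stimulus values, the
causal posterior is evaluated, and a trial counts as "illusion" when the
posterior probability of a common cause exceeds a threshold (0.5 by default).
A distance sweep moves the rubber hand away from the real hand and reports
where the illusion frequency first drops below one half.

The prior widths over latent position and time are "large numbers" that
approximate uniform priors, but the causal posterior depends on them through
the Occam factor, so their value is calibrated rather than guessed:
:func:`calibrate_prior_width` solves for the width at which a noise-free
synchronous trial at a chosen hand separation (default 300 mm, where the
illusion is known to fade) sits exactly at posterior 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .model import (
    InputError,
    ModelParams,
    ParameterError,
    SensorySample,
    model_averaged_estimates,
    posterior_common_cause,
)

__all__ = [
    "ConditionSpec",
    "SimulationResult",
    "SweepResult",
    "CalibrationError",
    "condition",
    "sample_sensations",
    "run_condition",
    "distance_sweep",
    "calibrate_prior_width",
]

#: time of the (first) brush stroke within a trial, ms.  With a
#: translation-invariant wide temporal prior its exact value is immaterial.
STROKE_TIME_MS = 1000.0

_CONDITION_NAMES = ("sync", "async", "no_stroke")


class CalibrationError(RuntimeError):
    """Raised when the prior-width root search fails; carries a diagnostic
    curve of (log sigma_x, log posterior odds) pairs."""

    def __init__(self, message: str, diagnostic=None):
        super().__init__(message)
        self.diagnostic = diagnostic


@dataclass(frozen=True)
class ConditionSpec:
    """Geometry and stroking schedule of one simulated condition.

    Defaults place the rubber hand 160 mm and the real hand 320 mm from the
    body midline, the layout used throughout.
    """

    name: str = "sync"
    true_x_v: float = 160.0          # rubber hand azimuth, mm
    true_x_p: float = 320.0          # real hand azimuth, mm
    temporal_offset: float = 0.0     # |tau_v - tau_t|, ms
    include_temporal: bool = True

    def validate(self, strict_offset: bool = True) -> None:
        if self.name not in _CONDITION_NAMES:
            raise InputError(
                f"unknown condition {self.name!r}; expected one of {_CONDITION_NAMES}"
            )
        for f_ in ("true_x_v", "true_x_p", "temporal_offset"):
            if not np.isfinite(getattr(self, f_)):
                raise InputError(f"{f_} must be finite")
        if self.name == "sync" and self.temporal_offset != 0.0:
            raise InputError("sync condition requires temporal_offset = 0")
        if self.name == "no_stroke" and self.include_temporal:
            raise InputError("no_stroke condition requires include_temporal = False")
        if (
            strict_offset
            and self.name == "async"
            and not (500.0 <= self.temporal_offset <= 1000.0)
        ):
            raise InputError(
                "async temporal_offset outside the admissible 500-1000 ms range; "
                "pass strict_offset=False to condition() to override"
            )


def condition(name: str, *, strict_offset: bool = True, **overrides) -> ConditionSpec:
    """Build a validated :class:`ConditionSpec` with per-condition defaults."""
    defaults = {
        "sync": dict(temporal_offset=0.0, include_temporal=True),
        "async": dict(temporal_offset=750.0, include_temporal=True),
        "no_stroke": dict(temporal_offset=0.0, include_temporal=False),
    }
    if name not in defaults:
        raise InputError(f"unknown condition {name!r}; expected one of {_CONDITION_NAMES}")
    kwargs = {**defaults[name], **overrides}
    spec = ConditionSpec(name=name, **kwargs)
    spec.validate(strict_offset=strict_offset)
    return spec


@dataclass(frozen=True)
class SimulationResult:
    """Aggregate outcome of one simulated condition."""

    condition: str
    n_trials: int
    p_illusion: float          # fraction of trials with p(C=1|cues) > threshold
    mean_p_c1: float
    mean_x_hat_v: float        # mm
    mean_x_hat_p: float        # mm
    mean_t_hat_v: Optional[float]   # ms, None without temporal dimension
    mean_t_hat_t: Optional[float]
    illusion_threshold: float
    seed: Optional[int]
    params: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SweepResult:
    """Illusion frequency as a function of hand separation."""

    distances: tuple          # mm, strictly increasing
    p_illusion: tuple
    vanish_distance: Optional[float]          # smallest tabulated d with p < 0.5, mm
    vanish_distance_interp: Optional[float]   # linear interpolation of the 0.5 crossing, mm
    n_trials_per_point: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# generative step
# ---------------------------------------------------------------------------


def sample_sensations(
    spec: ConditionSpec,
    params: ModelParams,
    rng: np.random.Generator,
    n: Optional[int] = None,
) -> SensorySample:
    """Draw noisy cues for ``n`` trials (or a single scalar trial).

    Cues are Gaussian around the true stimulus values with the model's own
    likelihood SDs: ``chi_v ~ N(true_x_v, sigma_v)``,
    ``chi_p ~ N(true_x_p, sigma_p)``; when strokes are present,
    ``tau_v ~ N(t0, sigma_tv)`` and ``tau_t ~ N(t0 + offset, sigma_tt)`` with
    the stroke time ``t0`` fixed at :data:`STROKE_TIME_MS`.
    """
    spec.validate(strict_offset=False)
    params.validate()
    size = None if n is None else int(n)
    chi_v = rng.normal(spec.true_x_v, params.sigma_v, size)
    chi_p = rng.normal(spec.true_x_p, params.sigma_p, size)
    if not spec.include_temporal:
        return SensorySample(chi_v=chi_v, chi_p=chi_p)
    tau_v = rng.normal(STROKE_TIME_MS, params.sigma_tv, size)
    tau_t = rng.normal(STROKE_TIME_MS + spec.temporal_offset, params.sigma_tt, size)
    return SensorySample(chi_v=chi_v, chi_p=chi_p, tau_v=tau_v, tau_t=tau_t)


# ---------------------------------------------------------------------------
# condition runs and the distance sweep
# ---------------------------------------------------------------------------


def _params_for(spec: ConditionSpec, params: ModelParams) -> ModelParams:
    if spec.include_temporal != params.include_temporal:
        return replace(params, include_temporal=spec.include_temporal)
    return params


def run_condition(
    spec: ConditionSpec,
    params: ModelParams,
    n_trials: int = 100_000,
    illusion_threshold: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationResult:
    """Monte Carlo run of one condition.

    Per trial: draw cues, evaluate the model-averaged estimates, record the
    causal posterior; a trial counts toward ``p_illusion`` when its posterior
    exceeds ``illusion_threshold``.  Bit-reproducible for a fixed ``seed``.
    """
    if n_trials < 1:
        raise InputError(f"n_trials must be >= 1, got {n_trials}")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = _params_for(spec, params)
    sample = sample_sensations(spec, p, rng, n=n_trials)
    est = model_averaged_estimates(sample, p)
    p_c1 = np.asarray(est.p_c1, dtype=float)
    return SimulationResult(
        condition=spec.name,
        n_trials=int(n_trials),
        p_illusion=float(np.mean(p_c1 > illusion_threshold)),
        mean_p_c1=float(np.mean(p_c1)),
        mean_x_hat_v=float(np.mean(est.x_hat_v)),
        mean_x_hat_p=float(np.mean(est.x_hat_p)),
        mean_t_hat_v=None if est.t_hat_v is None else float(np.mean(est.t_hat_v)),
        mean_t_hat_t=None if est.t_hat_t is None else float(np.mean(est.t_hat_t)),
        illusion_threshold=float(illusion_threshold),
        seed=seed,
        params=dataclasses.asdict(p),
    )


def distance_sweep(
    params: ModelParams,
    n_trials_per_point: int = 100_000,
    seed: Optional[int] = None,
    d_min: float = 160.0,
    d_max: float = 360.0,
    step: float = 20.0,
    sync: bool = True,
    true_x_p: float = 320.0,
    illusion_threshold: float = 0.5,
) -> SweepResult:
    """Sweep the rubber hand from ``d_min`` to ``d_max`` mm away from the real
    hand (default 160→360 mm in 20 mm steps, i.e. 16→36 cm in 2 cm steps),
    holding all other parameters constant.

    ``vanish_distance`` is the smallest tabulated separation at which the
    illusion frequency falls below one half; the linearly interpolated 0.5
    crossing between the adjacent grid points is reported alongside.
    Temporal input is synchronous by default.
    """
    if not d_min < d_max:
        raise InputError("d_min must be < d_max")
    if step <= 0:
        raise InputError("step must be > 0")
    distances = np.arange(d_min, d_max + 0.5 * step, step, dtype=float)
    if distances.size == 0:
        raise InputError("empty distance grid")
    # one child stream per grid point, all derived from the master seed
    seeds = np.random.SeedSequence(seed).spawn(distances.size)
    name = "sync" if sync else "no_stroke"
    p_ill = []
    for d, ss in zip(distances, seeds):
        spec = condition(name, true_x_v=true_x_p - float(d), true_x_p=true_x_p)
        res = run_condition(
            spec,
            params,
            n_trials=n_trials_per_point,
            illusion_threshold=illusion_threshold,
            rng=np.random.default_rng(ss),
        )
        p_ill.append(res.p_illusion)
    p_ill = np.asarray(p_ill)
    below = np.nonzero(p_ill < 0.5)[0]
    vanish = float(distances[below[0]]) if below.size else None
    interp = None
    if below.size and below[0] > 0:
        i = below[0]
        d0, d1 = distances[i - 1], distances[i]
        p0, p1 = p_ill[i - 1], p_ill[i]
        if p0 != p1:
            interp = float(d0 + (p0 - 0.5) * (d1 - d0) / (p0 - p1))
    elif below.size:
        interp = float(distances[0])
    return SweepResult(
        distances=tuple(float(d) for d in distances),
        p_illusion=tuple(float(p) for p in p_ill),
        vanish_distance=vanish,
        vanish_distance_interp=interp,
        n_trials_per_point=int(n_trials_per_point),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# prior-width calibration
# ---------------------------------------------------------------------------


def noise_free_posterior(
    separation_mm: float,
    params: ModelParams,
    true_x_p: float = 320.0,
    sync: bool = True,
) -> float:
    """Causal posterior for cues fixed at their true values (no sensory
    noise) at a given hand separation, with synchronous strokes."""
    if sync and params.include_temporal:
        sample = SensorySample(
            chi_v=true_x_p - separation_mm,
            chi_p=true_x_p,
            tau_v=STROKE_TIME_MS,
            tau_t=STROKE_TIME_MS,
        )
    else:
        params = replace(params, include_temporal=False)
        sample = SensorySample(chi_v=true_x_p - separation_mm, chi_p=true_x_p)
    return float(posterior_common_cause(sample, params))


def calibrate_prior_width(
    target_vanish_distance_mm: float = 300.0,
    params_template: Optional[ModelParams] = None,
    true_x_p: float = 320.0,
    log_bracket: tuple = (np.log(1.0e4), np.log(1.0e80)),
) -> ModelParams:
    """Solve for the prior widths that put the illusion boundary at a target
    hand separation.

    A one-dimensional root search on ``log sigma_x`` (with ``sigma_t`` moved
    by the same log-factor, preserving the template's ratio) finds the width
    at which the noise-free synchronous posterior at the target separation
    equals exactly 0.5.  The posterior is monotonically increasing in the
    prior width on the wide-prior branch, which the default bracket restricts
    the search to; a narrow prior can also favour a common cause when the
    cues sit far from the prior mean, so the global objective is not
    monotone and the bracket matters.

    Returns a copy of the template with calibrated ``sigma_x`` and ``sigma_t``.
    """
    if params_template is None:
        params_template = ModelParams()
    params_template.validate()
    if not (0.0 < target_vanish_distance_mm < true_x_p + 1e-9):
        raise ParameterError(
            "target vanish distance must be positive and no farther than the real hand"
        )
    tmpl = params_template
    if not (0.0 < tmpl.priors.p_common < 1.0):
        raise ParameterError("calibration requires 0 < p_common < 1")
    ratio_t = tmpl.priors.sigma_t / tmpl.priors.sigma_x

    def objective(log_sx: float) -> float:
        p = tmpl.with_priors(
            sigma_x=float(np.exp(log_sx)),
            sigma_t=float(ratio_t * np.exp(log_sx)),
        )
        sample_kw = dict(
            chi_v=true_x_p - target_vanish_distance_mm, chi_p=true_x_p
        )
        if p.include_temporal:
            sample_kw.update(tau_v=STROKE_TIME_MS, tau_t=STROKE_TIME_MS)
        s = SensorySample(**sample_kw)
        from .model import log_likelihood_common, log_likelihood_independent

        pc = p.priors.p_common
        # posterior log-odds; its root is exactly posterior = 0.5
        return float(
            log_likelihood_common(s, p)
            - log_likelihood_independent(s, p)
            + np.log(pc)
            - np.log1p(-pc)
        )

    lo, hi = log_bracket
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        grid = np.linspace(lo, hi, 25)
        raise CalibrationError(
            "no sign change in the calibration bracket "
            f"[{np.exp(lo):.3g}, {np.exp(hi):.3g}] mm",
            diagnostic=[(float(u), objective(float(u))) for u in grid],
        )
    root = optimize.brentq(objective, lo, hi, xtol=1e-13, rtol=1e-15)
    sigma_x = float(np.exp(root))
    return tmpl.with_priors(sigma_x=sigma_x, sigma_t=float(ratio_t * sigma_x))
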