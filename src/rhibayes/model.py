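"""Bayesian causal inference over spatiotemporal cues of the rubber hand illusion.

The observer receives four noisy cues on each trial: the seen position of the
rubber hand (``chi_v``) and the felt position of the real hand (``chi_p``) along
the azimuth, plus the seen and felt timing of a brush stroke (``tau_v``,
``tau_t``).  A binary latent variable ``C`` states whether all cues share one
environmental cause (the rubber hand *is* the observer's hand) or arise from
two independent causes.  Each causal structure implies a Gaussian marginal
likelihood of the cues; Bayes' rule gives the posterior probability of a
common cause, and squared-error loss makes the optimal position/timing
estimates posterior-weighted mixtures of the fused and segregated estimates
(model averaging).

Spatial and temporal cue pairs are assumed statistically independent, so each
marginal likelihood factorises into a spatial and a temporal term.  All
internal units are millimetres (space) and milliseconds (time); coordinates
are azimuthal with zero at the body midline, times are within-trial with zero
at trial start.  Every arithmetic path runs in log space so that the
cue discrepancies typical of the illusion (tens of likelihood SDs) do not
underflow.

All operations broadcast over numpy arrays, so a whole Monte Carlo batch of
samples can be evaluated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ParameterError",
    "InputError",
    "Priors",
    "ModelParams",
    "SensorySample",
    "EstimateSet",
    "log_likelihood_common",
    "log_likelihood_independent",
    "likelihood_common",
    "likelihood_independent",
    "posterior_common_cause",
    "fused_spatial_estimate",
    "fused_temporal_estimate",
    "segregated_estimates",
    "segregated_temporal_estimates",
    "model_averaged_estimates",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class ParameterError(ValueError):
    """A model parameter violates its constraints (e.g. non-positive SD)."""


class InputError(ValueError):
    """A sensory sample is inconsistent with the requested model structure."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Priors:
    """Priors over the latent position ``X`` and latent time ``T``.

    ``sigma_x`` / ``sigma_t`` are the widths of the (proper) Gaussian priors
    that stand in for the "uninformative" priors of the model: the improper
    flat limit is ill-defined in the causal posterior because the Occam factor
    of the independent-causes hypothesis grows with the prior width.  The
    shipped defaults are therefore calibrated (see
    :func:`rhibayes.simulate.calibrate_prior_width`), not hard-coded.
    """

    mu_x: float = 0.0          # mm, 0 = body midline
    sigma_x: float = 1.0e5     # mm
    mu_t: float = 0.0          # ms, 0 = trial start
    sigma_t: float = 1.0e5     # ms
    p_common: float = 0.5      # prior probability of a common cause

    def validate(self) -> None:
        for name in ("sigma_x", "sigma_t"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("mu_x", "mu_t"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        if not (0.0 <= self.p_common <= 1.0):
            raise ParameterError(f"p_common must lie in [0, 1], got {self.p_common!r}")


@dataclass(frozen=True)
class ModelParams:
    """Sensory noise SDs plus priors.

    Defaults are the values used throughout: visual spatial SD 1 mm,
    proprioceptive SD 15 mm, visual and tactile temporal SDs 20 ms, prior
    probability of a common cause 0.5.  When ``include_temporal`` is False the
    temporal dimension is dropped from every computation (the no-stroke
    variant of the model).
    """

    sigma_v: float = 1.0       # mm, visual spatial
    sigma_p: float = 15.0      # mm, proprioceptive spatial
    sigma_tv: float = 20.0     # ms, visual temporal
    sigma_tt: float = 20.0     # ms, tactile temporal
    priors: Priors = field(default_factory=Priors)
    include_temporal: bool = True

    def validate(self) -> None:
        for name in ("sigma_v", "sigma_p", "sigma_tv", "sigma_tt"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        self.priors.validate()

    def with_priors(self, **changes) -> "ModelParams":
        return replace(self, priors=replace(self.priors, **changes))


@dataclass(frozen=True)
class SensorySample:
    """One trial's noisy cues.  Temporal cues may be omitted when the model's
    temporal dimension is disabled; using such a sample with a temporal model
    is an error rather than a silent fallback."""

    chi_v: np.ndarray | float             # mm
    chi_p: np.ndarray | float             # mm
    tau_v: Optional[np.ndarray | float] = None   # ms
    tau_t: Optional[np.ndarray | float] = None   # ms

    def validate(self, params: ModelParams) -> None:
        for name in ("chi_v", "chi_p"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise InputError(f"{name} contains non-finite values")
        if params.include_temporal:
            if self.tau_v is None or self.tau_t is None:
                raise InputError(
                    "temporal cues are required when include_temporal is true; "
                    "request a spatial-only analysis explicitly via "
                    "ModelParams(include_temporal=False)"
                )
            for name in ("tau_v", "tau_t"):
                v = np.asarray(getattr(self, name), dtype=float)
                if not np.all(np.isfinite(v)):
                    raise InputError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class EstimateSet:
    """Posterior and optimal estimates for one sample (or a batch).

    ``x_hat_*`` are the model-averaged (posterior-mean, squared-error-optimal)
    estimates; the fused (common cause) and segregated (independent causes)
    components are reported alongside so either readout can be inspected.
    Temporal fields are ``None`` when the temporal dimension is disabled.
    """

    p_c1: np.ndarray | float
    x_hat_v: np.ndarray | float
    x_hat_p: np.ndarray | float
    x_fused: np.ndarray | float
    x_seg_v: np.ndarray | float
    x_seg_p: np.ndarray | float
    t_hat_v: Optional[np.ndarray | float] = None
    t_hat_t: Optional[np.ndarray | float] = None
    t_fused: Optional[np.ndarray | float] = None
    t_seg_v: Optional[np.ndarray | float] = None
    t_seg_t: Optional[np.ndarray | float] = None


# ---------------------------------------------------------------------------
# log-density primitives
# ---------------------------------------------------------------------------


def _log_norm(x, mu, sd):
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _log_pair_common(a, b, sd_a, sd_b, mu0, sd0):
    """log of the marginal density of two cues sharing one latent cause:

        integral  N(a; Z, sd_a) N(b; Z, sd_b) N(Z; mu0, sd0) dZ

    evaluated analytically.  With variances va, vb, v0 and
    D = va*vb + v0*(va + vb) the marginal is a bivariate Gaussian whose log is

        -log(2*pi) - log(D)/2
        - [ (a-b)^2 v0 + (a-mu0)^2 vb + (b-mu0)^2 va ] / (2 D)
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb, v0 = sd_a * sd_a, sd_b * sd_b, sd0 * sd0
    det = va * vb + v0 * (va + vb)
    quad = ((a - b) ** 2 * v0 + (a - mu0) ** 2 * vb + (b - mu0) ** 2 * va) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


def _log_pair_independent(a, b, sd_a, sd_b, mu0, sd0):
    """log marginal of two cues with independent latent causes sharing the
    same prior: product of two Gaussians with inflated variance."""
    return _log_norm(a, mu0, float(np.hypot(sd_a, sd0))) + _log_norm(
        b, mu0, float(np.hypot(sd_b, sd0))
    )


# ---------------------------------------------------------------------------
# likelihoods and posterior
# ---------------------------------------------------------------------------


def log_likelihood_common(sample: SensorySample, params: ModelParams):
    """Log marginal density of the cues under the common-cause hypothesis.

    The spatial and temporal factors multiply (the cue pairs are assumed
    statistically independent); each factor marginalises its latent variable
    analytically.
    """
    params.validate()
    sample.validate(params)
    pr = params.priors
    ll = _log_pair_common(
        sample.chi_v, sample.chi_p, params.sigma_v, params.sigma_p, pr.mu_x, pr.sigma_x
    )
    if params.include_temporal:
        ll = ll + _log_pair_common(
            sample.tau_v, sample.tau_t, params.sigma_tv, params.sigma_tt, pr.mu_t, pr.sigma_t
        )
    return ll


def log_likelihood_independent(sample: SensorySample, params: ModelParams):
    """Log marginal density under the independent-causes hypothesis: every cue
    is explained by its own latent draw from the prior."""
    params.validate()
    sample.validate(params)
    pr = params.priors
    ll = _log_pair_independent(
        sample.chi_v, sample.chi_p, params.sigma_v, params.sigma_p, pr.mu_x, pr.sigma_x
    )
    if params.include_temporal:
        ll = ll + _log_pair_independent(
            sample.tau_v, sample.tau_t, params.sigma_tv, params.sigma_tt, pr.mu_t, pr.sigma_t
        )
    return ll


def likelihood_common(sample: SensorySample, params: ModelParams):
    return np.exp(log_likelihood_common(sample, params))


def likelihood_independent(sample: SensorySample, params: ModelParams):
    return np.exp(log_likelihood_independent(sample, params))


def posterior_common_cause(sample: SensorySample, params: ModelParams):
    """Posterior probability that all cues share one cause.

    Computed as a logistic of the log likelihood-ratio plus log prior odds,
    which is exact and immune to underflow of the raw densities.
    """
    params.validate()
    pc = params.priors.p_common
    if pc in (0.0, 1.0):
        # the prior forces the causal structure regardless of the evidence
        sample.validate(params)
        shape = np.shape(np.asarray(sample.chi_v, dtype=float))
        out = np.full(shape, pc) if shape else float(pc)
        return out
    log_odds = (
        log_likelihood_common(sample, params)
        - log_likelihood_independent(sample, params)
        + np.log(pc)
        - np.log1p(-pc)
    )
    # logistic; clip keeps exp() in range, the result saturates exactly at 0/1
    return 1.0 / (1.0 + np.exp(np.clip(-log_odds, -745.0, 745.0)))


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------


def _precision_weighted(values, sds):
    num = sum(np.asarray(v, dtype=float) / (s * s) for v, s in zip(values, sds))
    den = sum(1.0 / (s * s) for s in sds)
    return num / den


def fused_spatial_estimate(sample: SensorySample, params: ModelParams):
    """Optimal position estimate under the common-cause hypothesis: the
    precision-weighted mean of the visual cue, the proprioceptive cue and the
    prior mean.  Identical for both modalities."""
    params.validate()
    sample.validate(params)
    pr = params.priors
    return _precision_weighted(
        (sample.chi_v, sample.chi_p, pr.mu_x),
        (params.sigma_v, params.sigma_p, pr.sigma_x),
    )


def fused_temporal_estimate(sample: SensorySample, params: ModelParams):
    """Temporal analog of :func:`fused_spatial_estimate`."""
    params.validate()
    if not params.include_temporal:
        raise InputError("temporal estimate requested with include_temporal=False")
    sample.validate(params)
    pr = params.priors
    return _precision_weighted(
        (sample.tau_v, sample.tau_t, pr.mu_t),
        (params.sigma_tv, params.sigma_tt, pr.sigma_t),
    )


def segregated_estimates(sample: SensorySample, params: ModelParams):
    """Per-modality position estimates under independent causes, returned as
    ``(visual, proprioceptive)``: each cue shrunk toward the prior mean by its
    own precision ratio."""
    params.validate()
    sample.validate(params)
    pr = params.priors
    x_v = _precision_weighted((sample.chi_v, pr.mu_x), (params.sigma_v, pr.sigma_x))
    x_p = _precision_weighted((sample.chi_p, pr.mu_x), (params.sigma_p, pr.sigma_x))
    return x_v, x_p


def segregated_temporal_estimates(sample: SensorySample, params: ModelParams):
    """Temporal analog of :func:`segregated_estimates`, ``(visual, tactile)``."""
    params.validate()
    if not params.include_temporal:
        raise InputError("temporal estimate requested with include_temporal=False")
    sample.validate(params)
    pr = params.priors
    t_v = _precision_weighted((sample.tau_v, pr.mu_t), (params.sigma_tv, pr.sigma_t))
    t_t = _precision_weighted((sample.tau_t, pr.mu_t), (params.sigma_tt, pr.sigma_t))
    return t_v, t_t


def model_averaged_estimates(sample: SensorySample, params: ModelParams) -> EstimateSet:
    """Full readout for one sample (or batch): causal posterior plus
    model-averaged estimates.

    Under squared-error loss on the position/timing estimates, the optimal
    estimate is the posterior mean, i.e. the mixture of the fused and
    segregated estimates weighted by the causal posterior — model averaging.
    Every averaged estimate therefore lies between its two components.
    """
    p1 = posterior_common_cause(sample, params)
    x_fused = fused_spatial_estimate(sample, params)
    x_seg_v, x_seg_p = segregated_estimates(sample, params)
    x_hat_v = p1 * x_fused + (1.0 - p1) * x_seg_v
    x_hat_p = p1 * x_fused + (1.0 - p1) * x_seg_p
    if not params.include_temporal:
        return EstimateSet(
            p_c1=p1, x_hat_v=x_hat_v, x_hat_p=x_hat_p,
            x_fused=x_fused, x_seg_v=x_seg_v, x_seg_p=x_seg_p,
        )
    t_fused = fused_temporal_estimate(sample, params)
    t_seg_v, t_seg_t = segregated_temporal_estimates(sample, params)
    return EstimateSet(
        p_c1=p1, x_hat_v=x_hat_v, x_hat_p=x_hat_p,
        x_fused=x_fused, x_seg_v=x_seg_v, x_seg_p=x_seg_p,
        t_hat_v=p1 * t_fused + (1.0 - p1) * t_seg_v,
        t_hat_t=p1 * t_fused + (1.0 - p1) * t_seg_t,
        t_fused=t_fused, t_seg_v=t_seg_v, t_seg_t=t_seg_t,
    )
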