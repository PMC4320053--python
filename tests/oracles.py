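"""Independent oracles used by the tests.

These deliberately avoid the package's closed forms: marginal likelihoods are
computed by adaptive quadrature over the latent variables, and the weighted
means by naive arithmetic, so agreement is a genuine cross-check.
"""

import numpy as np
from scipy import integrate, stats


def _peak_points(values, sds):
    """Break points bracketing the (narrow) peak of a Gaussian-product
    integrand, so adaptive quadrature cannot step over it when the
    surrounding interval is many orders of magnitude wider."""
    prec = np.array([1.0 / s**2 for s in sds])
    m = float(np.sum(prec * np.asarray(values, dtype=float)) / np.sum(prec))
    w = float(1.0 / np.sqrt(np.sum(prec)))
    return m, [m - 8 * w, m - w, m, m + w, m + 8 * w]


def quad_pair_common(a, b, sd_a, sd_b, mu0, sd0):
    """integral N(a; Z, sd_a) N(b; Z, sd_b) N(Z; mu0, sd0) dZ by adaptive
    quadrature."""
    def f(z):
        return (
            stats.norm.pdf(a, z, sd_a)
            * stats.norm.pdf(b, z, sd_b)
            * stats.norm.pdf(z, mu0, sd0)
        )
    span = 12 * max(sd_a, sd_b, sd0)
    lo = min(a, b, mu0) - span
    hi = max(a, b, mu0) + span
    _, pts = _peak_points([a, b, mu0], [sd_a, sd_b, sd0])
    pts = sorted(p for p in set([a, b, mu0, *pts]) if lo < p < hi)
    val, err = integrate.quad(
        f, lo, hi, epsabs=0.0, epsrel=1e-11, limit=500, points=pts
    )
    return val


def quad_marginal_single(x, sd_x, mu0, sd0):
    """integral N(x; Z, sd_x) N(Z; mu0, sd0) dZ by adaptive quadrature."""
    def f(z):
        return stats.norm.pdf(x, z, sd_x) * stats.norm.pdf(z, mu0, sd0)
    span = 12 * max(sd_x, sd0)
    lo, hi = min(x, mu0) - span, max(x, mu0) + span
    _, pts = _peak_points([x, mu0], [sd_x, sd0])
    pts = sorted(p for p in set([x, mu0, *pts]) if lo < p < hi)
    val, err = integrate.quad(
        f, lo, hi, epsabs=0.0, epsrel=1e-11, limit=500, points=pts,
    )
    return val


def quad_likelihood_common(sample, params):
    """Quadrature oracle for the common-cause marginal (spatial x temporal)."""
    pr = params.priors
    val = quad_pair_common(
        sample.chi_v, sample.chi_p, params.sigma_v, params.sigma_p, pr.mu_x, pr.sigma_x
    )
    if params.include_temporal:
        val *= quad_pair_common(
            sample.tau_v, sample.tau_t, params.sigma_tv, params.sigma_tt,
            pr.mu_t, pr.sigma_t,
        )
    return val


def quad_likelihood_independent(sample, params):
    """Quadrature oracle for the independent-causes marginal: each cue
    integrated against its own latent draw from the prior."""
    pr = params.priors
    val = quad_marginal_single(
        sample.chi_v, params.sigma_v, pr.mu_x, pr.sigma_x
    ) * quad_marginal_single(sample.chi_p, params.sigma_p, pr.mu_x, pr.sigma_x)
    if params.include_temporal:
        val *= quad_marginal_single(
            sample.tau_v, params.sigma_tv, pr.mu_t, pr.sigma_t
        ) * quad_marginal_single(sample.tau_t, params.sigma_tt, pr.mu_t, pr.sigma_t)
    return val


def weighted_mean_oracle(values, sds):
    """Precision-weighted mean by direct summation."""
    w = np.array([1.0 / s**2 for s in sds])
    v = np.asarray(values, dtype=float)
    return float(np.sum(w * v) / np.sum(w))


def random_draw(rng, include_temporal=True):
    """One random (sample, params) pair in the quadrature-friendly regime."""
    from rhibayes.model import ModelParams, Priors, SensorySample

    sd = lambda lo, hi: float(rng.uniform(lo, hi))
    priors = Priors(
        mu_x=float(rng.uniform(-50, 50)), sigma_x=sd(5, 500),
        mu_t=float(rng.uniform(-50, 50)), sigma_t=sd(5, 500),
        p_common=float(rng.uniform(0.05, 0.95)),
    )
    params = ModelParams(
        sigma_v=sd(0.5, 30), sigma_p=sd(0.5, 30),
        sigma_tv=sd(0.5, 50), sigma_tt=sd(0.5, 50),
        priors=priors, include_temporal=include_temporal,
    )
    def cue(mu0, s0, s):
        return float(rng.normal(mu0, np.hypot(s0, s)))
    sample = SensorySample(
        chi_v=cue(priors.mu_x, priors.sigma_x, params.sigma_v),
        chi_p=cue(priors.mu_x, priors.sigma_x, params.sigma_p),
        tau_v=cue(priors.mu_t, priors.sigma_t, params.sigma_tv) if include_temporal else None,
        tau_t=cue(priors.mu_t, priors.sigma_t, params.sigma_tt) if include_temporal else None,
    )
    return sample, params
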