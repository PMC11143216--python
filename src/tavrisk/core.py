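"""Complete-data probabilistic model.

Joint factorization over one patient:

    p(A, f, J, Y) = p(Y | A, f) . p(J | f) . p(f | A) . p(A)

with p(f|A) = N(f; beta^T A, sigma_I^2 I), p(J|f) = N(J; phi^T f, sigma_J^2 I),
p(Y|A,f) Bernoulli with logit alpha_I^T (f - beta^T A) + alpha_A^T A + b_Y, and
p(A) a product of per-dimension Gaussians (continuous) and Bernoullis (binary)
whose hyperparameters are fixed at their marginal maximum-likelihood values on
the training fold.  Isotropic covariances keep the parameter count compatible
with cohort-sized data sets.
"""

from __future__ import annotations

import numpy as np

from ._math import gauss_logpdf, log_sigmoid, sigmoid
from .schema import (
    RATE_CLIP,
    ModelParams,
    Observation,
    PriorParams,
    TabularSchema,
)

__all__ = [
    "fit_prior",
    "log_prior_observed",
    "outcome_logit",
    "outcome_probability",
    "complete_log_joint",
]


def fit_prior(A: np.ndarray, A_mask: np.ndarray, schema: TabularSchema) -> PriorParams:
    """Maximum-marginal-likelihood covariate prior from training rows.

    Continuous dimensions get the sample mean and the *ML* (biased) variance
    over their observed entries; binary dimensions get the observed fraction,
    clipped to [1e-3, 1-1e-3].  A dimension with no observed entry is an
    error — there is nothing to estimate from.
    """
    A = np.asarray(A, dtype=float)
    A_mask = np.asarray(A_mask, dtype=bool)
    d = schema.d_A
    mean = np.full(d, np.nan)
    var = np.full(d, np.nan)
    rate = np.full(d, np.nan)
    counts = A_mask.sum(axis=0)
    empty = np.where(counts == 0)[0]
    if empty.size:
        names = [schema.names[i] for i in empty]
        raise ValueError(f"covariate dimension(s) fully missing in training data: {names}")
    for i in schema.cont_idx:
        obs = A[A_mask[:, i], i]
        mean[i] = obs.mean()
        v = float(np.mean((obs - obs.mean()) ** 2))  # ML, not unbiased
        var[i] = max(v, 1e-6)
    for i in schema.bin_idx:
        obs = A[A_mask[:, i], i]
        rate[i] = float(np.clip(obs.mean(), RATE_CLIP, 1 - RATE_CLIP))
    prior = PriorParams(mean, var, rate)
    prior.validate(schema)
    return prior


def log_prior_observed(a, a_mask, prior: PriorParams, schema: TabularSchema):
    """log p(A_observed): sum of per-dimension prior log-densities.

    Vectorized over leading row axes of ``a``/``a_mask``.
    """
    a = np.asarray(a)
    a_mask = np.asarray(a_mask, dtype=bool)
    out = np.zeros(a.shape[:-1])
    ci = schema.cont_idx
    if ci.size:
        lp = gauss_logpdf(a[..., ci], prior.mean[ci], prior.var[ci])
        out = out + np.where(a_mask[..., ci], lp, 0.0).sum(axis=-1)
    bi = schema.bin_idx
    if bi.size:
        r = prior.rate[bi]
        lp = np.where(a[..., bi] > 0.5, np.log(r), np.log1p(-r))
        out = out + np.where(a_mask[..., bi], lp, 0.0).sum(axis=-1)
    return out


def outcome_logit(features, a, params: ModelParams):
    """alpha_I^T (f - beta^T a) + alpha_A^T a + b_Y (broadcasts over rows)."""
    features = np.asarray(features)
    a = np.asarray(a)
    resid = features - a @ params.beta
    return resid @ params.alpha_I + a @ params.alpha_A + params.b_Y


def outcome_probability(features, a, params: ModelParams):
    """P(Y=1 | A, f) for complete covariates and features."""
    return sigmoid(outcome_logit(features, a, params))


def complete_log_joint(obs: Observation, params: ModelParams,
                       prior: PriorParams, schema: TabularSchema) -> float:
    """Log of the complete-observation joint density, constants included.

    Written deliberately as the sum of the four factor log-densities so that
    it stays an independent reference for the marginalization code (which
    must reduce to it exactly when nothing is missing).
    """
    if not obs.fully_observed:
        raise ValueError(
            "observation has missing entries; use marginal_log_joint instead")
    f = obs.features
    a = obs.a
    z = outcome_logit(f, a, params)
    log_bern = log_sigmoid(z) if obs.y == 1 else log_sigmoid(-z)
    log_pj = float(np.sum(gauss_logpdf(obs.j, f @ params.phi, params.sigma_J**2)))
    log_pf = float(np.sum(gauss_logpdf(f, a @ params.beta, params.sigma_I**2)))
    log_pa = float(log_prior_observed(a, obs.a_mask, prior, schema))
    return float(log_bern) + log_pj + log_pf + log_pa
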