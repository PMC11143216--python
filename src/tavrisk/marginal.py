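"""Closed-form marginalization over missing covariates, images and measurements.

For an observation with missing entries the joint density of the *observed*
variables is obtained analytically:

* missing measurement dimensions are simply dropped (they are outputs);
* a missing image is integrated out of the linear-Gaussian hierarchy, turning
  p(J|A) into N(J; phi^T beta^T A, sigma_I^2 phi^T phi + sigma_J^2 I) and the
  outcome factor into a sigmoid of a Gaussian, handled with the scaled-probit
  approximation  E[sigma(g)] ~ sigma(E[g] / sqrt(1 + pi/8 Var[g]));
* missing continuous covariates are integrated against their Gaussian priors
  (they enter every factor linearly, so this stays in the Gaussian family);
* missing binary covariates are summed over {0,1} weighted by their prior
  rates — the outermost loop, with the Gaussian integrals done analytically
  inside each term and the terms combined by log-sum-exp.

With nothing missing the result reduces *exactly* to the complete-data
log-joint (the probit correction vanishes at zero variance).

The single evaluator :func:`pattern_core_log_density` is written to broadcast
over a leading parameter-batch axis; the training code exploits this to
evaluate many complex-step-perturbed parameter vectors in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._math import (
    LOG2PI,
    PROBIT_COEF,
    bit_combinations,
    gauss_logpdf,
    inv_spd,
    log_sigmoid,
    logsumexp,
    sigmoid,
    slogdet_sym,
)
from .core import complete_log_joint, log_prior_observed
from .schema import (
    MissingnessPattern,
    ModelParams,
    Observation,
    PriorParams,
    TabularSchema,
)

__all__ = [
    "sigmoid_gaussian_expectation",
    "marginal_log_joint",
    "predictive_outcome",
    "mc_marginal_oracle",
    "mc_predictive_oracle",
    "MCEstimate",
]

#: refuse enumeration beyond this many jointly-missing binary covariates
MAX_MISSING_BINARY = 20


def sigmoid_gaussian_expectation(mean, variance):
    """E[sigma(x)] for x ~ N(mean, variance), via the scaled-probit closure.

    Returns sigma(mean / sqrt(1 + (pi/8) variance)); exact at variance 0.
    """
    mean = np.asarray(mean)
    variance = np.asarray(variance)
    if np.any(np.real(variance) < 0):
        raise ValueError("variance must be non-negative")
    return sigmoid(mean / np.sqrt(1.0 + PROBIT_COEF * variance))


# ---------------------------------------------------------------------------
# batched parameter views
# ---------------------------------------------------------------------------

@dataclass
class BatchedParams:
    """ModelParams broadcast to one leading batch axis of size B.

    The batch axis carries complex-step perturbations during training; for
    plain evaluation B is 1.
    """

    beta: np.ndarray     # (B, d_A, d_f)
    phi: np.ndarray      # (B, d_f, d_J)
    sigma_I: np.ndarray  # (B,)
    sigma_J: np.ndarray  # (B,)
    alpha_I: np.ndarray  # (B, d_f)
    alpha_A: np.ndarray  # (B, d_A)
    b_Y: np.ndarray      # (B,)

    @classmethod
    def from_params(cls, p: ModelParams) -> "BatchedParams":
        return cls(
            beta=p.beta[None], phi=p.phi[None],
            sigma_I=np.atleast_1d(np.asarray(p.sigma_I)),
            sigma_J=np.atleast_1d(np.asarray(p.sigma_J)),
            alpha_I=p.alpha_I[None], alpha_A=p.alpha_A[None],
            b_Y=np.atleast_1d(np.asarray(p.b_Y)),
        )

    @property
    def B(self) -> int:
        return self.beta.shape[0]

    @property
    def d_f(self) -> int:
        return self.beta.shape[2]


def _eye(d, like):
    return np.eye(d, dtype=np.result_type(like, float))


def pattern_core_log_density(bp: BatchedParams, prior: PriorParams, *,
                             a: np.ndarray, y: np.ndarray,
                             mis_cont: np.ndarray, mis_bin: np.ndarray,
                             F=None, J_obs=None, j_obs_idx=None) -> np.ndarray:
    """Core log-density for a group of rows sharing one missingness pattern.

    Parameters
    ----------
    a : (n, d_A) covariate values; entries in ``mis_cont``/``mis_bin`` columns
        must be zero-filled (they are never read as data).
    y : (n,) outcomes in {0, 1}.
    F : (n, d_f) or (B, n, d_f) image features when the image is present,
        else None.
    J_obs, j_obs_idx : observed measurement values (n, O) and their column
        indices — only used (and required) when the image is missing; with
        the image present the measurement factor is separable per dimension
        and handled mask-wise by the caller.

    Returns
    -------
    (B, n) array:  log p(evidence, Y | A_obs) where evidence is F (image
    present) or J_obs (image missing).  Excludes log p(A_obs) and — for
    image-present rows — the measurement factor.
    """
    B = bp.B
    n, d_A = a.shape
    d_f = bp.d_f
    kc = len(mis_cont)
    kb = len(mis_bin)
    if kb > MAX_MISSING_BINARY:
        raise ValueError(
            f"{kb} jointly missing binary covariates exceeds the enumeration "
            f"limit of {MAX_MISSING_BINARY}")

    C = bit_combinations(kb)                      # (K, kb)
    K = C.shape[0]
    if kb:
        r = prior.rate[np.asarray(mis_bin, dtype=int)]
        logw = C @ np.log(r) + (1 - C) @ np.log1p(-r)   # (K,)
    else:
        logw = np.zeros(1)

    sig_I2 = bp.sigma_I**2                        # (B,)
    mu = prior.mean[np.asarray(mis_cont, dtype=int)] if kc else np.zeros(0)
    tau2 = prior.var[np.asarray(mis_cont, dtype=int)] if kc else np.zeros(0)
    beta_mc = bp.beta[:, np.asarray(mis_cont, dtype=int), :]   # (B, kc, d_f)
    beta_mb = bp.beta[:, np.asarray(mis_bin, dtype=int), :]    # (B, kb, d_f)

    # observed-covariate contributions (missing columns are zero-filled)
    base = np.einsum("nd,bdf->bnf", a, bp.beta)               # (B, n, d_f)
    lin_obs = np.einsum("nd,bd->bn", a, bp.alpha_A)           # (B, n)

    combo_f = np.einsum("Kk,bkf->bKf", C, beta_mb)            # (B, K, d_f)
    combo_lin = np.einsum("Kk,bk->bK", C, bp.alpha_A[:, np.asarray(mis_bin, dtype=int)])

    m_known = base[:, None, :, :] + combo_f[:, :, None, :]    # (B, K, n, d_f)
    mu_beta = np.einsum("c,bcf->bf", mu, beta_mc)             # (B, d_f)

    # covariance of f once the missing continuous dims are integrated out
    Cff = (sig_I2[:, None, None] * _eye(d_f, bp.beta)
           + np.einsum("bcf,c,bcg->bfg", beta_mc, tau2, beta_mc))

    # outcome-head coefficient on the latent a_mc block
    c_mc = (bp.alpha_A[:, np.asarray(mis_cont, dtype=int)]
            - np.einsum("bcf,bf->bc", beta_mc, bp.alpha_I))   # (B, kc)

    g_const = (lin_obs[:, None, :] + combo_lin[:, :, None]
               + bp.b_Y[:, None, None]
               - np.einsum("bknf,bf->bkn", m_known, bp.alpha_I))

    if F is not None:
        # ----- image present: evidence is f itself --------------------------
        F = np.asarray(F)
        if F.ndim == 2:
            F = np.broadcast_to(F, (B,) + F.shape)
        Sinv = inv_spd(Cff)
        logdetS = slogdet_sym(Cff)                            # (B,)
        evid_mean = m_known + mu_beta[:, None, None, :]
        res = F[:, None, :, :] - evid_mean
        quad = np.einsum("bknf,bfg,bkng->bkn", res, Sinv, res)
        log_evid = -0.5 * (d_f * LOG2PI + logdetS[:, None, None] + quad)

        # posterior over the missing continuous covariates given f
        f_term = np.einsum("bnf,bf->bn", F, bp.alpha_I)[:, None, :]
        if kc:
            Lam = (np.diag(1.0 / tau2)[None]
                   + np.einsum("bcf,bdf->bcd", beta_mc, beta_mc)
                   / sig_I2[:, None, None])
            Lam_inv = inv_spd(Lam)
            rres = F[:, None, :, :] - m_known
            eta = ((mu / tau2)
                   + np.einsum("bcf,bknf->bknc", beta_mc, rres)
                   / sig_I2[:, None, None, None])
            mu_post = np.einsum("bcd,bknd->bknc", Lam_inv, eta)
            Eg = g_const + f_term + np.einsum("bc,bknc->bkn", c_mc, mu_post)
            Vg = np.einsum("bc,bcd,bd->b", c_mc, Lam_inv, c_mc)
        else:
            Eg = g_const + f_term
            Vg = np.zeros(B, dtype=np.result_type(bp.beta, float))
    else:
        # ----- image missing: latent w = (a_mc, f) --------------------------
        d = kc + d_f
        dtype = np.result_type(bp.beta, float)
        Caf = tau2[:, None] * beta_mc if kc else np.zeros((B, 0, d_f), dtype=dtype)
        Caa = np.broadcast_to(np.diag(tau2), (B, kc, kc)) if kc else \
            np.zeros((B, 0, 0), dtype=dtype)
        top = np.concatenate([Caa.astype(dtype), Caf], axis=-1)
        bot = np.concatenate([np.swapaxes(Caf, -1, -2), Cff], axis=-1)
        C_w = np.concatenate([top, bot], axis=-2)              # (B, d, d)

        m_f = m_known + mu_beta[:, None, None, :]              # (B, K, n, d_f)
        m_w = np.concatenate(
            [np.broadcast_to(mu.astype(dtype), (B, K, n, kc)), m_f], axis=-1)
        c_w = np.concatenate([c_mc, bp.alpha_I], axis=-1)      # (B, d)

        O = 0 if j_obs_idx is None else len(j_obs_idx)
        if O:
            phiO = bp.phi[:, :, np.asarray(j_obs_idx, dtype=int)]  # (B, d_f, O)
            tmp = np.einsum("bfg,bgo->bfo", Cff, phiO)             # Cff phiO
            S_J = (np.einsum("bfo,bfp->bop", phiO, tmp)
                   + bp.sigma_J[:, None, None]**2 * _eye(O, bp.phi))
            S_J_inv = inv_spd(S_J)
            logdetJ = slogdet_sym(S_J)
            mean_J = np.einsum("bknf,bfo->bkno", m_f, phiO)
            dev = np.asarray(J_obs)[None, None, :, :] - mean_J
            quad = np.einsum("bkno,bop,bknp->bkn", dev, S_J_inv, dev)
            log_evid = -0.5 * (O * LOG2PI + logdetJ[:, None, None] + quad)
            G = np.concatenate(
                [np.einsum("bcf,bfo->bco", Caf, phiO), tmp], axis=-2)  # (B,d,O)
            Kg = np.einsum("bdo,bop->bdp", G, S_J_inv)
            m_post = m_w + np.einsum("bdo,bkno->bknd", Kg, dev)
            C_post = C_w - np.einsum("bdo,beo->bde", Kg, G)
        else:
            log_evid = np.zeros((B, 1, 1), dtype=dtype)
            m_post = m_w
            C_post = C_w
        Eg = g_const + np.einsum("bd,bknd->bkn", c_w, m_post)
        Vg = np.einsum("bd,bde,be->b", c_w, C_post, c_w)

    zeff = Eg / np.sqrt(1.0 + PROBIT_COEF * Vg[:, None, None])
    y = np.asarray(y)
    log_out = np.where(y[None, None, :] == 1, log_sigmoid(zeff),
                       log_sigmoid(-zeff))
    per_combo = logw[None, :, None] + log_evid + log_out
    return logsumexp(per_combo, axis=1)                        # (B, n)


# ---------------------------------------------------------------------------
# single-observation API
# ---------------------------------------------------------------------------

def _obs_core(obs: Observation, bp: BatchedParams, prior: PriorParams,
              schema: TabularSchema, y: int) -> np.ndarray:
    pat = MissingnessPattern.of(obs, schema)
    a = np.where(obs.a_mask, obs.a, 0.0)[None, :]
    yv = np.array([y])
    if obs.image_present:
        core = pattern_core_log_density(
            bp, prior, a=a, y=yv,
            mis_cont=np.asarray(pat.missing_cont_a, dtype=int),
            mis_bin=np.asarray(pat.missing_bin_a, dtype=int),
            F=obs.features[None, :],
        )
        j_safe = np.where(obs.j_mask, obs.j, 0.0)
        lp = gauss_logpdf(j_safe, obs.features @ bp.phi, bp.sigma_J[:, None]**2)
        core = core + np.where(obs.j_mask, lp, 0.0).sum(axis=-1)[:, None]
    else:
        j_obs_idx = np.where(obs.j_mask)[0]
        core = pattern_core_log_density(
            bp, prior, a=a, y=yv,
            mis_cont=np.asarray(pat.missing_cont_a, dtype=int),
            mis_bin=np.asarray(pat.missing_bin_a, dtype=int),
            F=None, J_obs=obs.j[j_obs_idx][None, :], j_obs_idx=j_obs_idx,
        )
    return core[:, 0]


def marginal_log_joint(obs: Observation, params: ModelParams,
                       prior: PriorParams, schema: TabularSchema) -> float:
    """log p(observed variables, Y) for an arbitrary missingness pattern.

    Reduces exactly to :func:`~tavrisk.core.complete_log_joint` when nothing
    is missing.  Requires the outcome; for outcome prediction use
    :func:`predictive_outcome`.
    """
    if obs.y is None:
        raise ValueError("outcome missing; use predictive_outcome for prediction")
    bp = BatchedParams.from_params(params)
    core = _obs_core(obs, bp, prior, schema, int(obs.y))
    lpa = log_prior_observed(np.where(obs.a_mask, obs.a, 0.0), obs.a_mask,
                             prior, schema)
    return float(core[0] + lpa)


def predictive_outcome(obs: Observation, params: ModelParams,
                       prior: PriorParams, schema: TabularSchema) -> float:
    """p(Y=1 | observed variables).

    With the image present this is the complete-data head (measurements are
    conditionally independent of Y given f and cancel from the ratio); with
    the image missing, observed measurements inform the outcome through the
    Gaussian posterior over f; with everything missing it falls back to the
    prior-marginal outcome probability.
    """
    bp = BatchedParams.from_params(params)
    l1 = _obs_core(obs, bp, prior, schema, 1)[0]
    l0 = _obs_core(obs, bp, prior, schema, 0)[0]
    return float(np.exp(l1 - np.logaddexp(l0, l1)))


# ---------------------------------------------------------------------------
# Monte-Carlo oracles
# ---------------------------------------------------------------------------

@dataclass
class MCEstimate:
    """Monte-Carlo estimate of a marginal density (probability scale)."""

    estimate: float
    stderr: float

    @property
    def log_estimate(self) -> float:
        return float(np.log(self.estimate))


def _sample_missing(obs, params, prior, schema, n_samples, rng):
    """Draw (A with missing dims sampled, f) from the generative priors."""
    pat = MissingnessPattern.of(obs, schema)
    a = np.tile(np.where(obs.a_mask, obs.a, 0.0), (n_samples, 1))
    for i in pat.missing_cont_a:
        a[:, i] = rng.normal(prior.mean[i], np.sqrt(prior.var[i]), n_samples)
    for i in pat.missing_bin_a:
        a[:, i] = rng.binomial(1, prior.rate[i], n_samples)
    if obs.image_present:
        f = np.tile(obs.features, (n_samples, 1))
    else:
        f = a @ params.beta + params.sigma_I * rng.standard_normal(
            (n_samples, params.d_f))
    return a, f, pat


def _log_weights(obs, params, a, f, y):
    """Per-sample log of the observed-data factors given sampled latents."""
    logw = np.zeros(a.shape[0])
    from .core import outcome_logit  # local import avoids cycle at module load

    z = outcome_logit(f, a, params)
    logw += log_sigmoid(z) if y == 1 else log_sigmoid(-z)
    j_safe = np.where(obs.j_mask, obs.j, 0.0)
    lp = gauss_logpdf(j_safe[None, :], f @ params.phi, params.sigma_J**2)
    logw += np.where(obs.j_mask[None, :], lp, 0.0).sum(axis=-1)
    if obs.image_present:
        logw += gauss_logpdf(obs.features[None, :], a @ params.beta,
                             params.sigma_I**2).sum(axis=-1)
    return logw


def mc_marginal_oracle(obs: Observation, params: ModelParams,
                       prior: PriorParams, schema: TabularSchema,
                       n_samples: int = 100_000, seed: int = 0) -> MCEstimate:
    """Monte-Carlo estimate of exp(marginal_log_joint), with standard error.

    Samples missing covariates (and the image features, when the image is
    missing) from their generative priors and averages the exact density of
    the observed variables — the logistic sigmoid is evaluated exactly, so
    this is an approximation-free reference for the closed form.  With no
    missing variables the marginal is deterministic and returned exactly with
    zero standard error.
    """
    if obs.y is None:
        raise ValueError("outcome missing; oracle needs a complete (obs, Y) pair")
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    pat = MissingnessPattern.of(obs, schema)
    nothing_sampled = (not pat.missing_cont_a and not pat.missing_bin_a
                       and obs.image_present)
    lpa = float(log_prior_observed(np.where(obs.a_mask, obs.a, 0.0),
                                   obs.a_mask, prior, schema))
    if nothing_sampled:
        return MCEstimate(np.exp(marginal_log_joint(obs, params, prior, schema)), 0.0)
    rng = np.random.default_rng(seed)
    a, f, _ = _sample_missing(obs, params, prior, schema, n_samples, rng)
    w = np.exp(_log_weights(obs, params, a, f, int(obs.y)) + lpa)
    est = float(w.mean())
    se = float(w.std(ddof=1) / np.sqrt(n_samples))
    return MCEstimate(est, se)


def mc_predictive_oracle(obs: Observation, params: ModelParams,
                         prior: PriorParams, schema: TabularSchema,
                         n_samples: int = 100_000, seed: int = 0) -> MCEstimate:
    """Monte-Carlo estimate of p(Y=1 | observed), with delta-method stderr.

    Self-normalized: E[sigma(g) w] / E[w] with w the likelihood of the
    observed measurements/features under the sampled latents.
    """
    rng = np.random.default_rng(seed)
    a, f, _ = _sample_missing(obs, params, prior, schema, n_samples, rng)
    from .core import outcome_logit

    # weights: all observed factors except the outcome
    logw = np.zeros(a.shape[0])
    j_safe = np.where(obs.j_mask, obs.j, 0.0)
    lp = gauss_logpdf(j_safe[None, :], f @ params.phi, params.sigma_J**2)
    logw += np.where(obs.j_mask[None, :], lp, 0.0).sum(axis=-1)
    if obs.image_present:
        logw += gauss_logpdf(obs.features[None, :], a @ params.beta,
                             params.sigma_I**2).sum(axis=-1)
    w = np.exp(logw - logw.max())
    s = sigmoid(outcome_logit(f, a, params))
    num, den = float(np.mean(s * w)), float(np.mean(w))
    est = num / den
    # delta method for the ratio of means
    cov = np.cov(np.stack([s * w, w]), ddof=1) / n_samples
    var = (cov[0, 0] - 2 * est * cov[0, 1] + est**2 * cov[1, 1]) / den**2
    return MCEstimate(est, float(np.sqrt(max(var, 0.0))))
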