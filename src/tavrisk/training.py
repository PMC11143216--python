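"""Joint maximum-likelihood training over a cohort with arbitrary missingness.

The objective is the mean negative marginal log-joint of each row under its
own missingness pattern (complete rows therefore use the full four-factor
log-joint, including the p(f|A) term, which ties beta to the data).  Rows are
grouped by missingness pattern so each group evaluates as one vectorized
closed-form expression.

Gradients of the probabilistic parameters are computed by *complex-step
differentiation*: the whole marginal-likelihood machinery is analytic in the
parameters, so evaluating it at theta + i*h*e_p and taking Im/h yields the
exact partial derivative with no subtractive cancellation.  All perturbed
parameter vectors are evaluated in one vectorized pass along a leading batch
axis (chunked to bound memory).  The tiny reference backbone is linear, so
its parameters get an exact analytic vector-Jacobian product instead.

sigma_I and sigma_J are optimized on the log scale; p(A) hyperparameters and
the per-fold scaler are fitted on training rows once and held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._math import log_sigmoid, logsumexp, sigmoid
from .backbone import ChunkCompressor, TinyBackbone, chunk_compress
from .core import fit_prior, log_prior_observed
from .marginal import BatchedParams, pattern_core_log_density
from .schema import Cohort, ModelParams, PriorParams, Scaler, TabularSchema

__all__ = [
    "TrainConfig",
    "FitResult",
    "ParamPacker",
    "prepare_data",
    "training_objective",
    "objective_and_grad",
    "fit_model",
    "fit_without_auxiliary",
    "predict_cohort",
]

_CSTEP_H = 1e-20


@dataclass
class TrainConfig:
    """Optimization settings; defaults favour cohort-scale robustness."""

    lr: float = 1e-3            # probabilistic parameters
    lr_backbone: float = 1e-4   # backbone + compressor parameters
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    use_auxiliary_J: bool = True
    image_inputs_enabled: bool = True
    init_scale: float = 0.01
    grad_chunk: int = 64        # complex-step vectors evaluated per pass
    lr_schedule: str = "constant"  # or "cosine" (decay to lr/20 by max_epochs)

    def __post_init__(self):
        if self.lr <= 0 or self.lr_backbone <= 0:
            raise ValueError("learning rates must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("batch size and epoch count must be positive")


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

class ParamPacker:
    """Flat real vector <-> ModelParams, noise scales on the log scale.

    With ``include_aux=False`` the measurement link (phi, sigma_J) is frozen
    at its initial value and excluded from the vector — the auxiliary-output
    component is then absent from the model entirely (its factors vanish
    because all J entries are masked).
    """

    def __init__(self, d_A: int, d_f: int, d_J: int, include_aux: bool = True,
                 frozen_phi=None, frozen_sigma_J: float = 1.0):
        self.d_A, self.d_f, self.d_J = d_A, d_f, d_J
        self.include_aux = include_aux
        self.frozen_phi = (np.zeros((d_f, d_J)) if frozen_phi is None
                           else np.asarray(frozen_phi))
        self.frozen_sigma_J = float(frozen_sigma_J)
        sizes = [d_A * d_f, d_f, d_A, 1, 1]
        if include_aux:
            sizes[1:1] = [d_f * d_J, 1]  # phi, log sigma_J after beta
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        self._slices = [slice(int(a), int(b))
                        for a, b in zip(bounds[:-1], bounds[1:])]
        self.n_params = int(bounds[-1])

    def pack(self, p: ModelParams) -> np.ndarray:
        parts = [p.beta.ravel()]
        if self.include_aux:
            parts += [p.phi.ravel(), [np.log(p.sigma_J)]]
        parts += [p.alpha_I, p.alpha_A, [p.b_Y], [np.log(p.sigma_I)]]
        return np.concatenate([np.asarray(x, dtype=float).ravel()
                               for x in parts])

    def unpack_batched(self, Theta: np.ndarray) -> BatchedParams:
        """(B, P) parameter matrix -> BatchedParams with leading axis B."""
        Theta = np.atleast_2d(Theta)
        B = Theta.shape[0]
        it = iter(self._slices)
        beta = Theta[:, next(it)].reshape(B, self.d_A, self.d_f)
        if self.include_aux:
            phi = Theta[:, next(it)].reshape(B, self.d_f, self.d_J)
            sigma_J = np.exp(Theta[:, next(it)][:, 0])
        else:
            phi = np.broadcast_to(self.frozen_phi, (B, self.d_f, self.d_J))
            sigma_J = np.full(B, self.frozen_sigma_J)
        alpha_I = Theta[:, next(it)]
        alpha_A = Theta[:, next(it)]
        b_Y = Theta[:, next(it)][:, 0]
        sigma_I = np.exp(Theta[:, next(it)][:, 0])
        return BatchedParams(beta=beta, phi=phi, sigma_I=sigma_I,
                             sigma_J=sigma_J, alpha_I=alpha_I,
                             alpha_A=alpha_A, b_Y=b_Y)

    def unpack(self, theta: np.ndarray) -> ModelParams:
        bp = self.unpack_batched(theta[None, :])
        return ModelParams(
            beta=np.real(bp.beta[0]).copy(), sigma_I=float(np.real(bp.sigma_I[0])),
            phi=np.real(bp.phi[0]).copy(), sigma_J=float(np.real(bp.sigma_J[0])),
            alpha_I=np.real(bp.alpha_I[0]).copy(),
            alpha_A=np.real(bp.alpha_A[0]).copy(),
            b_Y=float(np.real(bp.b_Y[0])))


# ---------------------------------------------------------------------------
# dataset preparation (grouping by missingness pattern)
# ---------------------------------------------------------------------------

@dataclass
class _Group:
    rows: np.ndarray            # indices into the cohort
    a: np.ndarray               # (m, d_A) zero-filled covariates
    y: np.ndarray               # (m,)
    mis_cont: np.ndarray
    mis_bin: np.ndarray
    image_present: bool
    f_pos: Optional[np.ndarray] = None    # positions into the feature matrix
    J_obs: Optional[np.ndarray] = None    # (m, O) observed measurement values
    j_obs_idx: Optional[np.ndarray] = None


@dataclass
class PreparedData:
    """Cohort arrays grouped by missingness pattern, in model units."""

    schema: TabularSchema
    n: int
    groups: list
    lpa: Optional[np.ndarray]   # (n,) log p(A_obs); filled once a prior exists
    J: np.ndarray               # (n_img rows kept aligned with img_rows)
    J_mask: np.ndarray
    img_rows: np.ndarray        # cohort row indices with images
    F: Optional[np.ndarray]     # (n_img, d_f) features for those rows
    y: np.ndarray
    A_filled: np.ndarray
    A_mask: np.ndarray
    row_ids: np.ndarray


def prepare_data(cohort: Cohort, use_auxiliary_J: bool = True,
                 prior: Optional[PriorParams] = None,
                 y_override: Optional[np.ndarray] = None) -> PreparedData:
    """Group rows of a (already scaled) cohort by missingness pattern."""
    schema = cohort.schema
    n = cohort.n
    if y_override is not None:
        y = np.broadcast_to(np.asarray(y_override, dtype=int), (n,)).copy()
    elif cohort.y is not None:
        y = cohort.y.astype(int)
    else:
        raise ValueError("cohort has no outcomes; pass y_override")
    A_filled = np.where(cohort.A_mask, np.nan_to_num(cohort.A), 0.0)
    J_mask = cohort.J_mask & use_auxiliary_J
    J_filled = np.where(J_mask, np.nan_to_num(cohort.J), 0.0)
    has_img = cohort.has_image.astype(bool)

    cont = set(schema.cont_idx.tolist())
    key_cols = np.concatenate(
        [cohort.A_mask, np.where(has_img[:, None], True, J_mask),
         has_img[:, None]], axis=1)
    _, first, inverse = np.unique(key_cols, axis=0, return_index=True,
                                  return_inverse=True)
    img_rows = np.where(has_img)[0]
    pos_of_row = np.full(n, -1)
    pos_of_row[img_rows] = np.arange(img_rows.size)

    groups = []
    for g in range(first.size):
        rows = np.where(inverse == g)[0]
        r0 = rows[0]
        miss = np.where(~cohort.A_mask[r0])[0]
        mis_cont = np.array([i for i in miss if i in cont], dtype=int)
        mis_bin = np.array([i for i in miss if i not in cont], dtype=int)
        image_present = bool(has_img[r0])
        if image_present:
            groups.append(_Group(rows=rows, a=A_filled[rows], y=y[rows],
                                 mis_cont=mis_cont, mis_bin=mis_bin,
                                 image_present=True, f_pos=pos_of_row[rows]))
        else:
            j_obs_idx = np.where(J_mask[r0])[0]
            groups.append(_Group(rows=rows, a=A_filled[rows], y=y[rows],
                                 mis_cont=mis_cont, mis_bin=mis_bin,
                                 image_present=False,
                                 J_obs=J_filled[np.ix_(rows, j_obs_idx)],
                                 j_obs_idx=j_obs_idx))
    lpa = None
    if prior is not None:
        lpa = np.asarray(log_prior_observed(A_filled, cohort.A_mask, prior,
                                            schema), dtype=float)
    F = None
    if cohort.F is not None and img_rows.size:
        F = np.nan_to_num(cohort.F[img_rows])
    return PreparedData(schema=schema, n=n, groups=groups, lpa=lpa,
                        J=J_filled[img_rows], J_mask=J_mask[img_rows],
                        img_rows=img_rows, F=F, y=y, A_filled=A_filled,
                        A_mask=cohort.A_mask, row_ids=cohort.ids)


def _log_joint_rows(bp: BatchedParams, prior: PriorParams, data: PreparedData,
                    F=None) -> np.ndarray:
    """(B, n) per-row log-joints.  ``F`` overrides data.F (may carry a batch
    axis for backbone feature flow)."""
    B = bp.B
    if F is None:
        F = data.F
    dtype = np.result_type(bp.beta, np.float64,
                           F if F is not None else np.float64)
    out = np.zeros((B, data.n), dtype=dtype)
    for g in data.groups:
        if g.image_present:
            Fg = F[..., g.f_pos, :]
            core = pattern_core_log_density(
                bp, prior, a=g.a, y=g.y, mis_cont=g.mis_cont,
                mis_bin=g.mis_bin, F=Fg)
        else:
            core = pattern_core_log_density(
                bp, prior, a=g.a, y=g.y, mis_cont=g.mis_cont,
                mis_bin=g.mis_bin, F=None, J_obs=g.J_obs,
                j_obs_idx=g.j_obs_idx)
        out[:, g.rows] = core
    if data.img_rows.size and data.J_mask.any():
        # measurement factor for image-present rows, separable per dimension
        mean = np.einsum("nf,bfj->bnj", F, bp.phi)
        var = bp.sigma_J[:, None, None] ** 2
        d = np.where(data.J_mask[None], data.J[None] - mean, 0.0)
        lp = -0.5 * (np.log(2 * np.pi * var) + d * d / var)
        out[:, data.img_rows] += np.where(data.J_mask[None], lp, 0.0).sum(axis=-1)
    if data.lpa is not None:
        out = out + data.lpa
    return out


def training_objective(data, params, prior: PriorParams,
                       use_auxiliary_J: bool = True) -> float:
    """Mean negative marginal log-joint of a cohort (already in model units).

    ``data`` may be a Cohort or a PreparedData; ``params`` a ModelParams.
    """
    if isinstance(data, Cohort):
        data = prepare_data(data, use_auxiliary_J=use_auxiliary_J, prior=prior)
    bp = BatchedParams.from_params(params)
    lj = _log_joint_rows(bp, prior, data)
    return float(-np.real(lj[0]).mean())


def objective_and_grad(theta: np.ndarray, packer: ParamPacker,
                       prior: PriorParams, data: PreparedData,
                       F=None, chunk: int = 64):
    """Objective value and exact gradient via vectorized complex step."""
    P = packer.n_params
    h = _CSTEP_H
    grad = np.empty(P)
    base = None
    for start in range(0, P + 1, chunk):
        stop = min(start + chunk, P + 1)
        Theta = np.tile(theta, (stop - start, 1)).astype(complex)
        for j, p in enumerate(range(start, stop)):
            if p >= 1:
                Theta[j, p - 1] += 1j * h
        bp = packer.unpack_batched(Theta)
        vals = -_log_joint_rows(bp, prior, data, F=F).mean(axis=1)
        if start == 0:
            base = float(np.real(vals[0]))
            grad[start:stop - 1] = np.imag(vals[1:]) / h
        else:
            grad[start - 1:stop - 1] = np.imag(vals) / h
    return base, grad


def feature_gradients(params: ModelParams, data: PreparedData,
                      include_feature_prior: bool = False) -> np.ndarray:
    """d(mean NLL)/dF for image rows — analytic, complete covariates required.

    Used to chain gradients into backbone parameters during joint training.
    By default the p(f|A) Gaussian term is *excluded* from the flow into the
    feature extractor (only the outcome and measurement terms steer omega):
    letting that term pull trainable features toward beta^T a admits a
    degenerate optimum where the extractor collapses its output onto the
    covariate prediction and sigma_I -> 0 sends the likelihood to infinity.
    The probabilistic parameters still see the full log-joint.
    """
    F = data.F
    grad = np.zeros_like(F)
    for g in data.groups:
        if not g.image_present:
            continue
        if g.mis_cont.size or g.mis_bin.size:
            raise ValueError(
                "joint backbone training requires complete covariates on "
                "image rows")
        f = F[g.f_pos]
        resid = f - g.a @ params.beta
        z = resid @ params.alpha_I + g.a @ params.alpha_A + params.b_Y
        mu = np.asarray(sigmoid(z), dtype=float)
        grad[g.f_pos] += (mu - g.y)[:, None] * params.alpha_I[None, :]
        if include_feature_prior:
            grad[g.f_pos] += resid / params.sigma_I**2
    if data.J_mask.any():
        mean = F @ params.phi
        dev = np.where(data.J_mask, mean - data.J, 0.0)
        grad += dev @ params.phi.T / params.sigma_J**2
    return grad / data.n


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one training run: best-validation parameters + traces."""

    params: ModelParams
    prior: PriorParams
    scaler_A: Scaler
    scaler_J: Scaler
    schema: TabularSchema
    config: TrainConfig
    train_trace: np.ndarray
    val_trace: np.ndarray
    stopped_epoch: int
    backbone: Optional[TinyBackbone] = None
    compressor: Optional[ChunkCompressor] = None

    @property
    def best_val(self) -> float:
        return float(np.min(self.val_trace))

    def scale_cohort(self, cohort: Cohort) -> Cohort:
        out = cohort.copy()
        out.A = self.scaler_A.transform(out.A)
        out.J = self.scaler_J.transform(out.J)
        return out

    def predict(self, cohort: Cohort) -> np.ndarray:
        """p(Y=1 | observed variables) per row, honouring missingness."""
        return predict_cohort(self.scale_cohort(cohort), self.params,
                              self.prior,
                              use_auxiliary_J=self.config.use_auxiliary_J)


def _scale_train(cohort: Cohort, schema: TabularSchema):
    scaler_A = Scaler.fit(cohort.A, cohort.A_mask, schema.cont_idx)
    # scale-only for J: the measurement link has no intercept to absorb a
    # centering offset, so centering would bias phi
    scaler_J = Scaler.fit(cohort.J, cohort.J_mask, np.arange(cohort.d_J),
                          with_center=False)
    return scaler_A, scaler_J


def _init_params(d_A, d_f, d_J, prevalence, config: TrainConfig) -> ModelParams:
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    eps = 1e-3
    prev = float(np.clip(prevalence, eps, 1 - eps))
    return ModelParams(
        beta=rng.normal(0, s, (d_A, d_f)), sigma_I=1.0,
        phi=rng.normal(0, s, (d_f, d_J)), sigma_J=1.0,
        alpha_I=rng.normal(0, s, d_f), alpha_A=rng.normal(0, s, d_A),
        b_Y=float(np.log(prev / (1 - prev))))


def _check_finite(loss, params, prior, data: PreparedData):
    if np.isfinite(loss):
        return
    bp = BatchedParams.from_params(params)
    lj = np.real(_log_joint_rows(bp, prior, data)[0])
    bad = data.row_ids[~np.isfinite(lj)]
    raise FloatingPointError(
        f"non-finite training objective; offending row ids: {bad.tolist()[:20]}")


def fit_model(train: Cohort, val: Cohort, config: TrainConfig,
              backbone: Optional[TinyBackbone] = None,
              compressor: Optional[ChunkCompressor] = None,
              images_train=None, images_val=None,
              d_f: Optional[int] = None) -> FitResult:
    """Gradient-based joint fit; early stopping on the validation objective.

    The scaler and the covariate prior are fitted on training rows only.
    With a backbone, ``images_*`` supply one 64^3 ROI per image-present row
    (in cohort order restricted to those rows) and the backbone + chunk
    compressor are trained jointly through their analytic VJP.

    Deterministic given ``config.seed``.
    """
    schema = train.schema
    if not config.image_inputs_enabled:
        train, val = train.without_images(), val.without_images()
    scaler_A, scaler_J = _scale_train(train, schema)

    def scaled(c):
        out = c.copy()
        out.A = scaler_A.transform(out.A)
        out.J = scaler_J.transform(out.J)
        return out

    train_s, val_s = scaled(train), scaled(val)
    prior = fit_prior(train_s.A, train_s.A_mask, schema)
    d_J = train.d_J
    if d_f is None:
        d_f = train.d_f if train.d_f is not None else (
            compressor.d_f if compressor is not None else 16)

    use_backbone = backbone is not None
    if use_backbone:
        if compressor is None:
            compressor = ChunkCompressor.init(backbone.embed_dim, d_f,
                                              seed=config.seed)
        from .backbone import preprocess_intensities

        def _pool_all(vols):
            if vols is None or not len(vols):
                return np.zeros((0, TinyBackbone.POOLED**3))
            return np.stack([TinyBackbone.pool(preprocess_intensities(v))
                             for v in vols])

        pooled_train = _pool_all(images_train)
        pooled_val = _pool_all(images_val)

    data_train = prepare_data(train_s, config.use_auxiliary_J, prior)
    data_val = prepare_data(val_s, config.use_auxiliary_J, prior)

    prevalence = train.y.mean()
    params0 = _init_params(schema.d_A, d_f, d_J, prevalence, config)
    packer = ParamPacker(schema.d_A, d_f, d_J,
                         include_aux=config.use_auxiliary_J,
                         frozen_phi=params0.phi, frozen_sigma_J=params0.sigma_J)
    theta = packer.pack(params0)

    if use_backbone:
        omega = np.concatenate([backbone.get_params(),
                                compressor.weights.copy()])
        n_bb = backbone.n_parameters
    else:
        omega = np.zeros(0)
        n_bb = 0

    def current_features(pooled, omega_vec):
        bb_W = omega_vec[:n_bb].reshape(backbone.W.shape)
        comp_w = omega_vec[n_bb:]
        emb = pooled @ bb_W.T
        comp = ChunkCompressor(comp_w, d_f)
        return emb, chunk_compress(emb, comp), comp

    # Adam state
    m_t = np.zeros(theta.size + omega.size)
    v_t = np.zeros_like(m_t)
    b1, b2, eps = 0.9, 0.999, 1e-8
    rng = np.random.default_rng(config.seed + 1)

    n = train_s.n
    full_batch = config.batch_size >= n
    train_trace, val_trace = [], []
    best = (np.inf, theta.copy(), omega.copy(), 0)
    step = 0
    train_cohort_scaled = train_s

    for epoch in range(config.max_epochs):
        if config.lr_schedule == "cosine":
            frac = epoch / max(config.max_epochs - 1, 1)
            lr_now = config.lr * (0.05 + 0.95 * 0.5
                                  * (1 + np.cos(np.pi * frac)))
        else:
            lr_now = config.lr
        if full_batch:
            batches = [None]
        else:
            perm = rng.permutation(n)
            batches = [perm[i:i + config.batch_size]
                       for i in range(0, n, config.batch_size)]
        epoch_losses = []
        for batch in batches:
            if batch is None:
                data_b = data_train
            else:
                data_b = prepare_data(train_cohort_scaled.subset(batch),
                                      config.use_auxiliary_J, prior)
            F_b = None
            if use_backbone:
                pooled_b = (pooled_train if batch is None else
                            pooled_train[_img_positions(train_s, batch)])
                emb_b, F_b, comp = current_features(pooled_b, omega)
            loss, g_theta = objective_and_grad(theta, packer, prior, data_b,
                                               F=F_b, chunk=config.grad_chunk)
            _check_finite(loss, packer.unpack(theta), prior, data_b)
            if use_backbone:
                g_F = feature_gradients(packer.unpack(theta),
                                        replace_F(data_b, F_b))
                cs = comp.chunk_size
                w = comp.weights.reshape(d_f, cs)
                g_emb = np.repeat(g_F, cs, axis=1) * np.tile(
                    w.ravel(), (g_F.shape[0], 1))
                g_bbW = backbone.vjp(pooled_b, g_emb)
                g_comp = (g_F[:, :, None]
                          * emb_b.reshape(-1, d_f, cs)).sum(axis=0).ravel()
                g_omega = np.concatenate([g_bbW.ravel(), g_comp])
            else:
                g_omega = np.zeros(0)
            g = np.concatenate([g_theta, g_omega])
            step += 1
            m_t = b1 * m_t + (1 - b1) * g
            v_t = b2 * v_t + (1 - b2) * g * g
            mh = m_t / (1 - b1**step)
            vh = v_t / (1 - b2**step)
            upd = mh / (np.sqrt(vh) + eps)
            theta = theta - lr_now * upd[:theta.size]
            if omega.size:
                omega = omega - config.lr_backbone * upd[theta.size:]
            epoch_losses.append(loss)
        train_trace.append(float(np.mean(epoch_losses)))

        F_val = None
        if use_backbone:
            _, F_val, _ = current_features(pooled_val, omega)
        bp = packer.unpack_batched(theta[None, :])
        val_loss = float(-np.real(
            _log_joint_rows(bp, prior, data_val, F=F_val)[0]).mean()) \
            if data_val.n else train_trace[-1]
        val_trace.append(val_loss)
        if val_loss < best[0] - 1e-12:
            best = (val_loss, theta.copy(), omega.copy(), epoch)
        elif epoch - best[3] >= config.patience:
            break

    theta_best, omega_best = best[1], best[2]
    params = packer.unpack(theta_best)
    bb_out, comp_out = None, None
    if use_backbone:
        bb_out = TinyBackbone(backbone.embed_dim)
        bb_out.set_params(omega_best[:n_bb])
        comp_out = ChunkCompressor(omega_best[n_bb:].copy(), d_f)
    return FitResult(params=params, prior=prior, scaler_A=scaler_A,
                     scaler_J=scaler_J, schema=schema, config=config,
                     train_trace=np.asarray(train_trace),
                     val_trace=np.asarray(val_trace),
                     stopped_epoch=len(train_trace) - 1,
                     backbone=bb_out, compressor=comp_out)


def _img_positions(cohort: Cohort, batch: np.ndarray) -> np.ndarray:
    """Positions (into the image-row feature matrix) of batch rows with images."""
    img_rows = np.where(cohort.has_image)[0]
    pos = {r: i for i, r in enumerate(img_rows)}
    return np.array([pos[r] for r in batch if r in pos], dtype=int)


def replace_F(data: PreparedData, F) -> PreparedData:
    return replace(data, F=np.asarray(np.real(F), dtype=float))


def fit_without_auxiliary(train: Cohort, val: Cohort, config: TrainConfig,
                          **kw) -> FitResult:
    """Ablation: the measurement component is removed from training and
    inference entirely (J never informs the fit or the predictions)."""
    return fit_model(train, val, replace(config, use_auxiliary_J=False), **kw)


# ---------------------------------------------------------------------------
# vectorized prediction
# ---------------------------------------------------------------------------

def predict_cohort(cohort: Cohort, params: ModelParams, prior: PriorParams,
                   use_auxiliary_J: bool = True) -> np.ndarray:
    """p(Y=1 | observed) for every row of an (already scaled) cohort."""
    bp = BatchedParams.from_params(params)
    d1 = prepare_data(cohort, use_auxiliary_J, prior,
                      y_override=np.ones(cohort.n, dtype=int))
    d0 = prepare_data(cohort, use_auxiliary_J, prior,
                      y_override=np.zeros(cohort.n, dtype=int))
    l1 = np.real(_log_joint_rows(bp, prior, d1)[0])
    l0 = np.real(_log_joint_rows(bp, prior, d0)[0])
    return np.exp(l1 - np.logaddexp(l0, l1))
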