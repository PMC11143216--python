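"""Model/Results interface in the idiom of statistical modelling packages.

``TavrRiskModel`` is built from data (a :class:`~tavrisk.schema.Cohort` or a
DataFrame); ``fit()`` runs the joint maximum-likelihood training and returns
a ``TavrRiskResults`` carrying the estimates, convergence diagnostics, an
optional observed-information covariance for the outcome head, prediction,
simulation and plotting.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .schema import Cohort, ModelParams, Scaler, TabularSchema
from .training import (
    FitResult,
    ParamPacker,
    TrainConfig,
    objective_and_grad,
    prepare_data,
    fit_model,
)

__all__ = ["TavrRiskModel", "TavrRiskResults"]


class TavrRiskModel:
    """Probabilistic tabular+image mortality model bound to a cohort.

    Parameters
    ----------
    cohort : Cohort
        Training data (may contain any missingness pattern).
    val_fraction : float
        Share of rows held out, stratified by outcome, for early stopping.
    d_f : int, optional
        Feature dimension when the cohort carries no feature matrix.
    use_auxiliary : bool
        Keep the measurement component p(J|f) in the likelihood.
    """

    def __init__(self, cohort: Cohort, val_fraction: float = 0.125,
                 d_f: Optional[int] = None, use_auxiliary: bool = True):
        if cohort.y is None:
            raise ValueError("training requires outcomes")
        self.cohort = cohort
        self.val_fraction = float(val_fraction)
        self.d_f = d_f
        self.use_auxiliary = bool(use_auxiliary)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: TabularSchema,
                       **kw) -> "TavrRiskModel":
        """Build from a cohort DataFrame (measurement columns ``J_*``,
        outcome column ``y``; blank/NaN entries are treated as missing)."""
        from .io import cohort_from_dataframe

        return cls(cohort_from_dataframe(df, schema), **kw)

    def _split(self, seed: int):
        rng = np.random.default_rng(seed)
        y = self.cohort.y
        val = np.zeros(self.cohort.n, dtype=bool)
        for cls_ in np.unique(y):
            idx = np.where(y == cls_)[0]
            k = max(1, int(round(idx.size * self.val_fraction)))
            val[rng.choice(idx, size=k, replace=False)] = True
        return np.where(~val)[0], np.where(val)[0]

    def fit(self, config: Optional[TrainConfig] = None, seed: int = 0,
            **overrides) -> "TavrRiskResults":
        config = config or TrainConfig(seed=seed)
        if overrides:
            config = replace(config, **overrides)
        config = replace(config, use_auxiliary_J=self.use_auxiliary,
                         seed=config.seed if config.seed is not None else seed)
        tr, va = self._split(config.seed)
        res = fit_model(self.cohort.subset(tr), self.cohort.subset(va),
                        config, d_f=self.d_f)
        return TavrRiskResults(self, res)


class TavrRiskResults:
    """Fitted model: estimates, diagnostics, prediction and plotting."""

    def __init__(self, model: TavrRiskModel, fit: FitResult):
        self.model = model
        self.fit_result = fit

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> ModelParams:
        return self.fit_result.params

    @property
    def schema(self) -> TabularSchema:
        return self.fit_result.schema

    @property
    def llf(self) -> float:
        """Best validation mean log-likelihood (per observation)."""
        return -self.fit_result.best_val

    @property
    def converged(self) -> bool:
        return self.fit_result.stopped_epoch < self.fit_result.config.max_epochs - 1

    def predict(self, data) -> np.ndarray:
        """p(Y=1 | observed) for a Cohort or cohort DataFrame."""
        if isinstance(data, pd.DataFrame):
            from .io import cohort_from_dataframe

            data = cohort_from_dataframe(data, self.schema,
                                         require_outcome=False)
        return self.fit_result.predict(data)

    def simulate(self, n: int, seed: int = 0) -> Cohort:
        """Sample a synthetic cohort from the fitted generative model."""
        from .synthetic import TrueModel, generate_cohort

        truth = TrueModel(self.schema, self.params, self.fit_result.prior)
        return generate_cohort(truth, n, seed=seed)

    # -- uncertainty -------------------------------------------------------

    def cov_params(self, ridge: float = 1e-8) -> np.ndarray:
        """Observed-information covariance of the flat parameter vector.

        Hessian by central differences of the (exact) complex-step gradient;
        intended for the cohort the model was built on.  O(P) gradient
        evaluations — fine at tabular scale, expensive for very large P.
        """
        fr = self.fit_result
        packer = ParamPacker(self.schema.d_A, self.params.d_f,
                             self.params.d_J,
                             include_aux=fr.config.use_auxiliary_J,
                             frozen_phi=self.params.phi,
                             frozen_sigma_J=self.params.sigma_J)
        theta = packer.pack(self.params)
        cohort = fr.scale_cohort(self.model.cohort)
        data = prepare_data(cohort, fr.config.use_auxiliary_J, fr.prior)
        P = packer.n_params
        H = np.empty((P, P))
        h = 1e-5
        for p in range(P):
            tp, tm = theta.copy(), theta.copy()
            tp[p] += h
            tm[p] -= h
            _, gp = objective_and_grad(tp, packer, fr.prior, data)
            _, gm = objective_and_grad(tm, packer, fr.prior, data)
            H[p] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T) * self.model.cohort.n  # objective is mean NLL
        self._packer = packer
        return np.linalg.inv(H + ridge * np.eye(P))

    def bse(self) -> pd.Series:
        """Approximate standard errors of the covariate weights alpha_A."""
        cov = self.cov_params()
        packer = self._packer
        # alpha_A block location inside the flat vector
        off = self.schema.d_A * self.params.d_f
        if packer.include_aux:
            off += self.params.d_f * self.params.d_J + 1
        off += self.params.d_f
        se = np.sqrt(np.diag(cov)[off:off + self.schema.d_A])
        return pd.Series(se, index=list(self.schema.names), name="bse")

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        p = self.params
        fr = self.fit_result
        lines = []
        lines.append("TAVR mortality risk model — maximum likelihood")
        lines.append("=" * 58)
        lines.append(f"observations: {self.model.cohort.n}    "
                     f"d_A={p.d_A}  d_f={p.d_f}  d_J={p.d_J}")
        lines.append(f"epochs run: {fr.stopped_epoch + 1}   "
                     f"val NLL/obs: {fr.best_val:.4f}   "
                     f"converged: {self.converged}")
        lines.append(f"sigma_I: {p.sigma_I:.4f}   sigma_J: {p.sigma_J:.4f}   "
                     f"b_Y: {p.b_Y:+.4f}   |alpha_I|: "
                     f"{np.linalg.norm(p.alpha_I):.4f}")
        lines.append(f"auxiliary measurements: "
                     f"{'on' if fr.config.use_auxiliary_J else 'off'}")
        lines.append("-" * 58)
        lines.append(f"{'covariate':<32}{'kind':<12}{'alpha_A':>12}")
        for name, kind, w in zip(self.schema.names, self.schema.kinds,
                                 p.alpha_A):
            lines.append(f"{name:<32}{kind:<12}{w:>12.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<TavrRiskResults n={self.model.cohort.n} "
                f"val_nll={self.fit_result.best_val:.4f}>")

    # -- plots -------------------------------------------------------------

    def plot_convergence(self, ax=None):
        """Training / validation objective traces per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fr = self.fit_result
        ax.plot(fr.train_trace, label="train")
        ax.plot(fr.val_trace, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("negative log-likelihood / obs")
        ax.legend()
        return ax

    def plot_roc(self, cohort: Cohort, ax=None):
        """ROC curve of the fitted model on a given cohort."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        if ax is None:
            _, ax = plt.subplots()
        scores = self.predict(cohort)
        fpr, tpr, _ = roc_curve(cohort.y, scores)
        ax.plot(fpr, tpr)
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax
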