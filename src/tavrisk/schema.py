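"""Domain containers: covariate schema, priors, model parameters, cohorts.

The model ties four blocks of variables together: tabular baseline
characteristics ``A`` (mixed continuous/binary), a low-dimensional image
representation ``f`` extracted from a straightened aortic ROI, manual CT
measurements ``J`` used as auxiliary outputs, and a binary outcome ``Y``
(all-cause mortality during follow-up).  The containers below carry those
blocks plus per-entry observedness masks; a masked entry has no numeric
meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"

#: Bernoulli rates are clipped into this range so degenerate training folds
#: can never produce -inf log-probabilities.
RATE_CLIP = 1e-3

#: Measurement columns in cohort CSV files carry this prefix.
J_PREFIX = "J_"


@dataclass(frozen=True)
class TabularSchema:
    """Names and kinds of the covariate vector ``A``.

    ``kinds[i]`` is ``"continuous"`` or ``"binary"``; names must be unique.
    """

    names: tuple
    kinds: tuple

    def __post_init__(self):
        names = tuple(self.names)
        kinds = tuple(self.kinds)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "kinds", kinds)
        if len(names) != len(kinds):
            raise ValueError("names and kinds must have equal length")
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        bad = [k for k in kinds if k not in (CONTINUOUS, BINARY)]
        if bad:
            raise ValueError(f"unknown covariate kinds: {bad}")

    @property
    def d_A(self) -> int:
        return len(self.names)

    @property
    def cont_idx(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == CONTINUOUS], dtype=int)

    @property
    def bin_idx(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == BINARY], dtype=int)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown covariate {name!r}") from None

    def to_dict(self) -> dict:
        return {"names": list(self.names), "kinds": list(self.kinds)}

    @classmethod
    def from_dict(cls, d: dict) -> "TabularSchema":
        return cls(tuple(d["names"]), tuple(d["kinds"]))


@dataclass
class PriorParams:
    """Fixed hyperparameters of the covariate prior p(A).

    Per continuous dimension a Gaussian (mean, var); per binary dimension a
    Bernoulli rate clipped to [1e-3, 1-1e-3].  Entries for the other kind are
    NaN.  These are fitted once per training fold by maximum marginal
    likelihood and then held fixed during gradient training.
    """

    mean: np.ndarray
    var: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if not (self.mean.shape == self.var.shape == self.rate.shape):
            raise ValueError("prior arrays must share one shape (d_A,)")

    @property
    def d_A(self) -> int:
        return self.mean.shape[0]

    def validate(self, schema: TabularSchema) -> None:
        ci, bi = schema.cont_idx, schema.bin_idx
        if ci.size and not np.all(self.var[ci] > 0):
            raise ValueError("continuous prior variances must be positive")
        if bi.size and not np.all(
            (self.rate[bi] >= RATE_CLIP) & (self.rate[bi] <= 1 - RATE_CLIP)
        ):
            raise ValueError("binary prior rates must lie in the clipped range")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "var": self.var.tolist(),
            "rate": self.rate.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorParams":
        return cls(np.array(d["mean"]), np.array(d["var"]), np.array(d["rate"]))


@dataclass
class ModelParams:
    """Parameters of the generative links and the logistic outcome head.

    beta    : (d_A, d_f) map from covariates to the image-feature mean
    sigma_I : isotropic feature noise scale (>= 0)
    phi     : (d_f, d_J) map from features to the measurement mean
    sigma_J : isotropic measurement noise scale (>= 0)
    alpha_I : (d_f,) feature weights in the outcome head
    alpha_A : (d_A,) covariate weights in the outcome head
    b_Y     : intercept

    The outcome head reads sigma(alpha_I^T (f - beta^T a) + alpha_A^T a + b_Y):
    the image contributes through the *residual* of f around its covariate
    prediction, so tabular and image effects are not double counted.
    """

    beta: np.ndarray
    sigma_I: float
    phi: np.ndarray
    sigma_J: float
    alpha_I: np.ndarray
    alpha_A: np.ndarray
    b_Y: float

    def __post_init__(self):
        self.beta = np.asarray(self.beta)
        self.phi = np.asarray(self.phi)
        self.alpha_I = np.asarray(self.alpha_I)
        self.alpha_A = np.asarray(self.alpha_A)
        if self.beta.ndim != 2 or self.phi.ndim != 2:
            raise ValueError("beta and phi must be matrices")
        if self.beta.shape[1] != self.phi.shape[0]:
            raise ValueError("beta (d_A,d_f) and phi (d_f,d_J) disagree on d_f")
        if self.alpha_I.shape != (self.beta.shape[1],):
            raise ValueError("alpha_I must have length d_f")
        if self.alpha_A.shape != (self.beta.shape[0],):
            raise ValueError("alpha_A must have length d_A")
        if np.real(self.sigma_I) < 0 or np.real(self.sigma_J) < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def d_A(self) -> int:
        return self.beta.shape[0]

    @property
    def d_f(self) -> int:
        return self.beta.shape[1]

    @property
    def d_J(self) -> int:
        return self.phi.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.beta.copy(), float(self.sigma_I), self.phi.copy(),
            float(self.sigma_J), self.alpha_I.copy(), self.alpha_A.copy(),
            float(self.b_Y),
        )

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "sigma_I": float(self.sigma_I),
            "phi": self.phi.tolist(),
            "sigma_J": float(self.sigma_J),
            "alpha_I": self.alpha_I.tolist(),
            "alpha_A": self.alpha_A.tolist(),
            "b_Y": float(self.b_Y),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            np.array(d["beta"]), d["sigma_I"], np.array(d["phi"]),
            d["sigma_J"], np.array(d["alpha_I"]), np.array(d["alpha_A"]),
            d["b_Y"],
        )


@dataclass
class Scaler:
    """Training-fold z-scoring for continuous dimensions.

    Binary dimensions keep center 0 / scale 1, continuous dimensions get the
    observed training mean and standard deviation (floored away from zero).
    Fitted on training rows only — never on validation or test rows.
    """

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scales must be positive")

    @classmethod
    def fit(cls, values: np.ndarray, mask: np.ndarray, cont_idx: np.ndarray,
            with_center: bool = True) -> "Scaler":
        """``with_center=False`` gives scale-only normalization — used for
        the measurements J, whose linear link carries no intercept term that
        could absorb a centering offset."""
        values = np.asarray(values, dtype=float)
        d = values.shape[1]
        center = np.zeros(d)
        scale = np.ones(d)
        for i in np.atleast_1d(cont_idx):
            obs = values[mask[:, i], i]
            if obs.size == 0:
                continue
            if with_center:
                center[i] = obs.mean()
            sd = obs.std()
            scale[i] = sd if sd > 1e-8 else 1.0
        return cls(center, scale)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scale + self.center

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(np.array(d["center"]), np.array(d["scale"]))


@dataclass
class Observation:
    """One patient: covariates, measurements, optional image features, outcome.

    ``features`` must be set iff ``image_present``; ``y`` may be None at
    prediction time.  Masked entries carry no numeric meaning.
    """

    a: np.ndarray
    a_mask: np.ndarray
    j: np.ndarray
    j_mask: np.ndarray
    image_present: bool
    features: Optional[np.ndarray] = None
    y: Optional[int] = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.a_mask = np.asarray(self.a_mask, dtype=bool)
        self.j = np.asarray(self.j, dtype=float)
        self.j_mask = np.asarray(self.j_mask, dtype=bool)
        if self.image_present and self.features is None:
            raise ValueError("image_present requires features")
        if not self.image_present and self.features is not None:
            raise ValueError("features given although image_present is False")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)

    @property
    def fully_observed(self) -> bool:
        return (
            bool(self.a_mask.all())
            and bool(self.j_mask.all())
            and self.image_present
            and self.y is not None
        )


@dataclass(frozen=True)
class MissingnessPattern:
    """Index sets of unobserved variables, derived from Observation masks."""

    missing_cont_a: tuple
    missing_bin_a: tuple
    missing_j: tuple
    image_missing: bool

    @classmethod
    def of(cls, obs: Observation, schema: TabularSchema) -> "MissingnessPattern":
        miss = ~obs.a_mask
        mc = tuple(int(i) for i in schema.cont_idx if miss[i])
        mb = tuple(int(i) for i in schema.bin_idx if miss[i])
        mj = tuple(int(i) for i in np.where(~obs.j_mask)[0])
        return cls(mc, mb, mj, not obs.image_present)

    @property
    def empty(self) -> bool:
        return not (self.missing_cont_a or self.missing_bin_a or self.missing_j
                    or self.image_missing)


class Cohort:
    """Column-oriented container for a set of observations.

    Arrays: ``A`` (n, d_A) with NaN where unobserved, ``A_mask`` bool,
    ``J``/``J_mask`` likewise, ``has_image`` (n,), ``F`` (n, d_f) feature
    rows (NaN where the image is missing), and optional outcome ``y``.
    """

    def __init__(self, schema, A, A_mask, J, J_mask, has_image, F=None, y=None,
                 ids=None):
        self.schema = schema
        self.A = np.asarray(A, dtype=float)
        self.A_mask = np.asarray(A_mask, dtype=bool)
        self.J = np.asarray(J, dtype=float)
        self.J_mask = np.asarray(J_mask, dtype=bool)
        self.has_image = np.asarray(has_image, dtype=bool)
        n = self.A.shape[0]
        self.F = None if F is None else np.asarray(F, dtype=float)
        self.y = None if y is None else np.asarray(y, dtype=int)
        self.ids = (np.arange(n) if ids is None
                    else np.asarray(ids))
        if self.A.shape != self.A_mask.shape:
            raise ValueError("A and A_mask shapes differ")
        if self.J.shape != self.J_mask.shape:
            raise ValueError("J and J_mask shapes differ")
        # F may be None even when has_image is set: features can be attached
        # later or computed on the fly by a backbone during training.

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def d_J(self) -> int:
        return self.J.shape[1]

    @property
    def d_f(self) -> Optional[int]:
        return None if self.F is None else self.F.shape[1]

    def row(self, i: int) -> Observation:
        has_img = bool(self.has_image[i])
        if has_img and self.F is None:
            raise ValueError("row has an image but features are not attached")
        return Observation(
            a=self.A[i], a_mask=self.A_mask[i], j=self.J[i], j_mask=self.J_mask[i],
            image_present=has_img,
            features=self.F[i] if has_img else None,
            y=None if self.y is None else int(self.y[i]),
        )

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            self.schema, self.A[idx], self.A_mask[idx], self.J[idx],
            self.J_mask[idx], self.has_image[idx],
            None if self.F is None else self.F[idx],
            None if self.y is None else self.y[idx],
            self.ids[idx],
        )

    def copy(self) -> "Cohort":
        return self.subset(np.arange(self.n))

    # --- masking helpers used by predictor-importance ---------------------

    def with_masked_covariates(self, names: Sequence[str]) -> "Cohort":
        out = self.copy()
        for name in names:
            out.A_mask[:, self.schema.index_of(name)] = False
        return out

    def with_masked_measurements(self, j_idx: Sequence[int]) -> "Cohort":
        out = self.copy()
        for j in j_idx:
            out.J_mask[:, int(j)] = False
        return out

    def without_images(self) -> "Cohort":
        out = self.copy()
        out.has_image[:] = False
        return out

    def without_measurements(self) -> "Cohort":
        out = self.copy()
        out.J_mask[:] = False
        return out

    # --- DataFrame round trip --------------------------------------------

    def to_dataframe(self, j_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        cols = {}
        cols["patient_id"] = self.ids
        for i, name in enumerate(self.schema.names):
            col = np.where(self.A_mask[:, i], self.A[:, i], np.nan)
            cols[name] = col
        jn = j_names or [f"{J_PREFIX}{i}" for i in range(self.d_J)]
        for i, name in enumerate(jn):
            cols[name] = np.where(self.J_mask[:, i], self.J[:, i], np.nan)
        if self.y is not None:
            cols["y"] = self.y
        return pd.DataFrame(cols)

    @classmethod
    def from_arrays_complete(cls, schema, A, J, y, F=None) -> "Cohort":
        """Build a fully-observed cohort (masks all true)."""
        A = np.asarray(A, dtype=float)
        J = np.asarray(J, dtype=float)
        has_image = np.full(A.shape[0], F is not None)
        return cls(schema, A, np.ones_like(A, dtype=bool), J,
                   np.ones_like(J, dtype=bool), has_image, F, y)
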