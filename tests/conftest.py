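import numpy as np
import pytest

from tavrisk.schema import ModelParams, PriorParams, TabularSchema, Observation
from tavrisk.synthetic import MissingnessSpec, generate_cohort, impose_missingness, \
    make_true_params


@pytest.fixture(scope="session")
def small_schema():
    return TabularSchema(("age", "bmi", "diabetes", "male"),
                         ("continuous", "continuous", "binary", "binary"))


@pytest.fixture(scope="session")
def small_instance(small_schema):
    """A fixed (params, prior) pair at d_A=4, d_f=3, d_J=2."""
    rng = np.random.default_rng(42)
    params = ModelParams(
        beta=rng.normal(0, 0.5, (4, 3)), sigma_I=1.1,
        phi=rng.normal(0, 0.5, (3, 2)), sigma_J=0.6,
        alpha_I=rng.normal(0, 0.7, 3), alpha_A=rng.normal(0, 0.7, 4),
        b_Y=0.3)
    prior = PriorParams(
        mean=np.array([0.1, -0.2, np.nan, np.nan]),
        var=np.array([1.2, 0.8, np.nan, np.nan]),
        rate=np.array([np.nan, np.nan, 0.3, 0.6]))
    return params, prior


def sample_observation(rng, params, prior, a_mask=(1, 1, 1, 1),
                       j_mask=(1, 1), image=True, y=None):
    """Draw one observation from the generative hierarchy, then mask it."""
    a = np.array([rng.normal(prior.mean[0], np.sqrt(prior.var[0])),
                  rng.normal(prior.mean[1], np.sqrt(prior.var[1])),
                  float(rng.random() < prior.rate[2]),
                  float(rng.random() < prior.rate[3])])
    f = a @ params.beta + params.sigma_I * rng.standard_normal(params.d_f)
    j = f @ params.phi + params.sigma_J * rng.standard_normal(params.d_J)
    am = np.asarray(a_mask, dtype=bool)
    jm = np.asarray(j_mask, dtype=bool)
    return Observation(a=np.where(am, a, np.nan), a_mask=am,
                       j=np.where(jm, j, np.nan), j_mask=jm,
                       image_present=bool(image),
                       features=f if image else None,
                       y=int(rng.random() < 0.5) if y is None else y)


@pytest.fixture(scope="session")
def masked_cohort():
    """A small mixed-missingness cohort with known generating truth."""
    truth = make_true_params(4, 3, 3, effect_scale=1.5, seed=3)
    complete = generate_cohort(truth, 400, seed=5)
    masked = impose_missingness(
        complete, MissingnessSpec(rate_a=0.3, rate_j=0.3, image_rate=0.49),
        seed=6)
    return truth, complete, masked
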