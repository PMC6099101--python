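"""Synthetic rating data with the exact structure the G-study assumes.

Scores follow the additive crossed random-effects model

    X_pir = mu + nu_p + nu_i + nu_r + nu_pi + nu_pr + nu_ir + e_pir

with every effect drawn independently from a zero-mean normal with its
specified variance.  Defaults mirror the study conditions the package
analyses: 80 persons, 2 items per task family, 3 raters, a 1-5 rating scale
centred near 3, and (at response level) a per-person fluency of about 6.5
responses per item.

Continuous scores are the default: the estimation theory is moment-based
and averaged ratings are near-continuous.  ``discretize=True`` clips to
[1, 5] and rounds to integers, which biases component recovery (documented
in docs/methods.md) and is therefore opt-in.

Response-level tables draw fluency from a zero-truncated Poisson and give
each response an integer 1-5 rating whose cell expectation follows the
score-level model; averaging those ratings back into cell scores shrinks
the residual by the fluency, so response-level recovery is qualitative by
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import RATING_MAX, RATING_MIN, SCORE_COLUMNS
from .gstudy import (
    COMPONENT_NAMES,
    VarianceComponents,
    estimate_variance_components,
    mean_squares_array,
)

__all__ = ["SimulationSpec", "simulate_scores", "simulate_response_level", "parameter_recovery"]

_DEFAULT_COMPONENTS = VarianceComponents(0.167, 0.069, 0.181, 0.139, 0.008, 0.021, 0.096)


@dataclass(frozen=True)
class SimulationSpec:
    """True component variances, design sizes, and seed for one simulation.

    Defaults reproduce the per-family study design (80 persons, 2 items,
    3 raters) with reference average-rating components as truth; the same
    seed always yields a bit-identical table.
    """

    true_components: VarianceComponents = _DEFAULT_COMPONENTS
    grand_mean: float = 3.0
    n_p: int = 80
    n_i: int = 2
    n_r: int = 3
    seed: int = 0
    discretize: bool = False
    fluency_mean: float = 6.5
    family: str = "alternative_uses"
    item_prefix: str = field(default="item", repr=False)

    def __post_init__(self) -> None:
        if min(self.n_p, self.n_i, self.n_r) < 1:
            raise ValueError("design sizes must be >= 1")
        if any(v < 0 for v in self.true_components.as_dict().values()):
            raise ValueError("true component variances must be non-negative")
        if self.fluency_mean <= 0:
            raise ValueError("fluency_mean must be positive")


def _effects(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Systematic part of the score cube: all effects except the residual."""
    c = spec.true_components
    n_p, n_i, n_r = spec.n_p, spec.n_i, spec.n_r
    sd = {k: np.sqrt(v) for k, v in c.as_dict().items()}
    x = np.full((n_p, n_i, n_r), spec.grand_mean)
    x += rng.normal(0.0, sd["p"], n_p)[:, None, None]
    x += rng.normal(0.0, sd["i"], n_i)[None, :, None]
    x += rng.normal(0.0, sd["r"], n_r)[None, None, :]
    x += rng.normal(0.0, sd["pi"], (n_p, n_i))[:, :, None]
    x += rng.normal(0.0, sd["pr"], (n_p, n_r))[:, None, :]
    x += rng.normal(0.0, sd["ri"], (n_i, n_r))[None, :, :]
    return x


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{k + 1:0{width}d}" for k in range(n)]


def _cube_to_table(cube: np.ndarray, spec: SimulationSpec) -> pd.DataFrame:
    persons = _labels("p", spec.n_p)
    items = _labels(spec.item_prefix, spec.n_i)
    raters = _labels("rater", spec.n_r)
    idx = pd.MultiIndex.from_product(
        [persons, items, raters], names=["person_id", "item_id", "rater_id"]
    )
    df = idx.to_frame(index=False)
    df["family"] = spec.family
    df["score"] = cube.reshape(-1)
    return df[SCORE_COLUMNS]


def simulate_scores(spec: SimulationSpec) -> pd.DataFrame:
    """Draw one balanced score table from the crossed random-effects model."""
    rng = np.random.default_rng(spec.seed)
    cube = _effects(spec, rng)
    cube = cube + rng.normal(
        0.0, np.sqrt(spec.true_components.sigma2_pir_e), (spec.n_p, spec.n_i, spec.n_r)
    )
    if spec.discretize:
        cube = np.clip(np.rint(cube), RATING_MIN, RATING_MAX)
    return _cube_to_table(cube, spec)


def _zt_poisson_rate(mean: float) -> float:
    """Rate lambda of a zero-truncated Poisson with the given mean."""
    if mean <= 1.0:
        raise ValueError("a zero-truncated Poisson has mean > 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return float(optimize.brentq(f, 1e-9, mean + 10.0))


def _zt_poisson(rate: float, size: int, rng: np.random.Generator) -> np.ndarray:
    # inverse-CDF sampling restricted to k >= 1
    u = rng.uniform(stats.poisson.cdf(0, rate), 1.0, size=size)
    return stats.poisson.ppf(u, rate).astype(int)


def simulate_response_level(spec: SimulationSpec) -> pd.DataFrame:
    """Draw a response-level ratings table.

    Fluency per (person, item) is zero-truncated Poisson with mean
    ``spec.fluency_mean``.  Every rater rates every response; the rating is
    the cell's systematic value plus fresh residual noise per response,
    rounded and clipped to the integer 1-5 scale.
    """
    rng = np.random.default_rng(spec.seed)
    cell = _effects(spec, rng)
    rate = _zt_poisson_rate(spec.fluency_mean)
    fluency = _zt_poisson(rate, spec.n_p * spec.n_i, rng).reshape(spec.n_p, spec.n_i)
    persons = _labels("p", spec.n_p)
    items = _labels(spec.item_prefix, spec.n_i)
    raters = _labels("rater", spec.n_r)
    resid_sd = np.sqrt(spec.true_components.sigma2_pir_e)
    rows = []
    for p in range(spec.n_p):
        for i in range(spec.n_i):
            for k in range(fluency[p, i]):
                noise = rng.normal(0.0, resid_sd, spec.n_r)
                ratings = np.clip(np.rint(cell[p, i] + noise), RATING_MIN, RATING_MAX)
                for r in range(spec.n_r):
                    rows.append(
                        (persons[p], spec.family, items[i], raters[r], f"resp{k + 1}", int(ratings[r]))
                    )
    return pd.DataFrame(
        rows, columns=["person_id", "family", "item_id", "rater_id", "response_id", "rating"]
    )


def parameter_recovery(spec: SimulationSpec, n_reps: int) -> pd.DataFrame:
    """Monte-Carlo recovery of the G-study estimator under a known truth.

    Repeats simulate -> ANOVA mean squares -> EMS solve ``n_reps`` times
    (per-replicate seeds derived from ``spec.seed``) and summarises each
    component's mean estimate, bias, replicate SD, and standard error.
    Estimates are taken untruncated so bias is assessed on the raw moment
    estimator.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_reps) % (2**31)
    estimates = np.empty((n_reps, len(COMPONENT_NAMES)))
    for rep, s in enumerate(seeds):
        rep_spec = replace(spec, seed=int(s))
        rng = np.random.default_rng(rep_spec.seed)
        cube = _effects(rep_spec, rng) + rng.normal(
            0.0,
            np.sqrt(spec.true_components.sigma2_pir_e),
            (spec.n_p, spec.n_i, spec.n_r),
        )
        if spec.discretize:
            cube = np.clip(np.rint(cube), RATING_MIN, RATING_MAX)
        vc = estimate_variance_components(mean_squares_array(cube))
        estimates[rep] = [vc.raw[name] for name in COMPONENT_NAMES]
    truth = np.array([spec.true_components.as_dict()[name] for name in COMPONENT_NAMES])
    mean_est = estimates.mean(axis=0)
    rep_sd = estimates.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "component": COMPONENT_NAMES,
            "truth": truth,
            "mean_estimate": mean_est,
            "bias": mean_est - truth,
            "mean_abs_error": np.abs(estimates - truth).mean(axis=0),
            "replicate_sd": rep_sd,
            "se_mean": rep_sd / np.sqrt(n_reps),
        }
    )
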