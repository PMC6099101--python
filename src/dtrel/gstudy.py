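"""G-study: variance-component estimation for the crossed p x i x r design.

Observed scores are modelled by the additive random-effects decomposition

    X_pir = mu + nu_p + nu_i + nu_r + nu_pi + nu_pr + nu_ir + e_pir

with persons (p) the object of measurement and items (i) and raters (r)
random facets.  The three-way interaction is confounded with residual error,
giving seven estimable variance components: sigma2(p), sigma2(i), sigma2(r),
sigma2(pi), sigma2(pr), sigma2(ri), sigma2(pir,e).

Estimation is the closed-form expected-mean-squares (Henderson / ANOVA)
method for balanced designs: compute the classical three-way ANOVA mean
squares, then invert their expectations.  Negative solutions — a known
artefact of moment estimation — are kept raw for diagnostics and truncated
to zero for reporting, which is also how published component tables print
them.  Unbalanced tables are refused (REML would be needed; see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .data_model import Design, RatingValidationError, validate_balanced, validate_score_table

__all__ = [
    "COMPONENT_NAMES",
    "MeanSquares",
    "VarianceComponents",
    "mean_squares",
    "mean_squares_array",
    "score_array",
    "estimate_variance_components",
    "gstudy",
    "percent_variance",
    "components_table",
]

# canonical reporting order, matching published G-study tables
COMPONENT_NAMES = ("p", "i", "r", "pi", "pr", "ri", "pir_e")

_EFFECTS = ("p", "i", "r", "pi", "pr", "ir", "pir")


@dataclass(frozen=True)
class MeanSquares:
    """Balanced three-way ANOVA mean squares and degrees of freedom."""

    ms: dict[str, float]
    df: dict[str, int]
    design: Design

    def __getitem__(self, effect: str) -> float:
        return self.ms[effect]


@dataclass(frozen=True)
class VarianceComponents:
    """The seven variance components of the p x i x r random model.

    Reported fields are truncated at zero; ``raw`` keeps the untruncated
    EMS solutions for diagnostics.  ``sigma2_p`` is the universe-score
    variance when persons are the object of measurement.
    """

    sigma2_p: float
    sigma2_i: float
    sigma2_r: float
    sigma2_pi: float
    sigma2_pr: float
    sigma2_ri: float
    sigma2_pir_e: float
    label: str = ""
    raw: dict[str, float] = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, "sigma2_" + name) for name in COMPONENT_NAMES}

    def total(self) -> float:
        return float(sum(self.as_dict().values()))

    def with_label(self, label: str) -> "VarianceComponents":
        return replace(self, label=label)

    @classmethod
    def from_dict(cls, d: dict[str, float], label: str = "") -> "VarianceComponents":
        known = {f.name for f in fields(cls)}
        kw = {("sigma2_" + k if "sigma2_" + k in known else k): float(v) for k, v in d.items()}
        return cls(label=label, **kw)


def score_array(scores: pd.DataFrame) -> tuple[np.ndarray, Design]:
    """Pivot a balanced score table into a (n_p, n_i, n_r) array."""
    scores = validate_score_table(scores)
    design = validate_balanced(scores)
    design.require_gstudy()
    cube = scores.pivot_table(
        index="person_id", columns=["item_id", "rater_id"], values="score", sort=True
    )
    arr = cube.to_numpy().reshape(design.n_p, design.n_i, design.n_r)
    return arr, design


def mean_squares_array(x: np.ndarray) -> MeanSquares:
    """Classical balanced three-way ANOVA mean squares from a (P, I, R) array.

    Sums of squares are built from the marginal-mean deviations that define
    each effect; dividing by the effect's degrees of freedom gives the mean
    square.  The seven effect SS add up to the total SS exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected a 3-d (person, item, rater) array, got shape {x.shape}")
    n_p, n_i, n_r = x.shape
    if min(n_p, n_i, n_r) < 2:
        raise RatingValidationError(
            f"need >= 2 levels per facet for ANOVA mean squares, got shape {x.shape}"
        )
    grand = x.mean()
    m_p = x.mean(axis=(1, 2))
    m_i = x.mean(axis=(0, 2))
    m_r = x.mean(axis=(0, 1))
    m_pi = x.mean(axis=2)
    m_pr = x.mean(axis=1)
    m_ir = x.mean(axis=0)

    ss = {
        "p": n_i * n_r * np.sum((m_p - grand) ** 2),
        "i": n_p * n_r * np.sum((m_i - grand) ** 2),
        "r": n_p * n_i * np.sum((m_r - grand) ** 2),
        "pi": n_r * np.sum((m_pi - m_p[:, None] - m_i[None, :] + grand) ** 2),
        "pr": n_i * np.sum((m_pr - m_p[:, None] - m_r[None, :] + grand) ** 2),
        "ir": n_p * np.sum((m_ir - m_i[:, None] - m_r[None, :] + grand) ** 2),
    }
    resid = (
        x
        - m_pi[:, :, None]
        - m_pr[:, None, :]
        - m_ir[None, :, :]
        + m_p[:, None, None]
        + m_i[None, :, None]
        + m_r[None, None, :]
        - grand
    )
    ss["pir"] = np.sum(resid**2)

    df = {
        "p": n_p - 1,
        "i": n_i - 1,
        "r": n_r - 1,
        "pi": (n_p - 1) * (n_i - 1),
        "pr": (n_p - 1) * (n_r - 1),
        "ir": (n_i - 1) * (n_r - 1),
        "pir": (n_p - 1) * (n_i - 1) * (n_r - 1),
    }
    ms = {eff: float(ss[eff] / df[eff]) for eff in _EFFECTS}
    return MeanSquares(ms=ms, df=df, design=Design(n_p, n_i, n_r, balanced=True))


def mean_squares(scores: pd.DataFrame) -> MeanSquares:
    """ANOVA mean squares from a balanced long-format score table."""
    arr, _ = score_array(scores)
    return mean_squares_array(arr)


def estimate_variance_components(ms: MeanSquares, label: str = "") -> VarianceComponents:
    """Solve the expected-mean-squares equations of the crossed random model.

    For the balanced p x i x r random model the expectations are

        E[MS_pir] = s2(pir,e)
        E[MS_pi]  = s2(pir,e) + n_r s2(pi)        (and symmetrically pr, ir)
        E[MS_p]   = s2(pir,e) + n_r s2(pi) + n_i s2(pr) + n_i n_r s2(p)

    whose inversion is closed-form.  Raw (possibly negative) solutions are
    preserved in ``raw``; reported components are truncated at zero.
    """
    n_p, n_i, n_r = ms.design.n_p, ms.design.n_i, ms.design.n_r
    raw = {
        "pir_e": ms["pir"],
        "pi": (ms["pi"] - ms["pir"]) / n_r,
        "pr": (ms["pr"] - ms["pir"]) / n_i,
        "ri": (ms["ir"] - ms["pir"]) / n_p,
        "p": (ms["p"] - ms["pi"] - ms["pr"] + ms["pir"]) / (n_i * n_r),
        "i": (ms["i"] - ms["pi"] - ms["ir"] + ms["pir"]) / (n_p * n_r),
        "r": (ms["r"] - ms["pr"] - ms["ir"] + ms["pir"]) / (n_p * n_i),
    }
    truncated = {"sigma2_" + name: max(0.0, raw[name]) for name in COMPONENT_NAMES}
    return VarianceComponents(**truncated, label=label, raw=raw)


def gstudy(scores: pd.DataFrame, label: str = "") -> VarianceComponents:
    """Full G-study on a balanced score table: mean squares then EMS solve."""
    return estimate_variance_components(mean_squares(scores), label=label)


def percent_variance(vc: VarianceComponents) -> dict[str, float]:
    """Percent of total variance per component (truncated components)."""
    total = vc.total()
    if total <= 0:
        raise RatingValidationError("all variance components are zero; percentages undefined")
    return {name: 100.0 * value / total for name, value in vc.as_dict().items()}


def components_table(vc: VarianceComponents) -> pd.DataFrame:
    """Component estimates and percent of variance in reporting layout.

    Estimates print to 3 decimals and percentages to 1 decimal in the
    formatted CSV; this frame keeps full precision.
    """
    pct = percent_variance(vc)
    comp = vc.as_dict()
    return pd.DataFrame(
        {
            "component": list(COMPONENT_NAMES),
            "estimate": [comp[n] for n in COMPONENT_NAMES],
            "percent": [pct[n] for n in COMPONENT_NAMES],
        }
    )
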