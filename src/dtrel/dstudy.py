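"""D-study: project G-study components to candidate designs and score them.

A decision study asks how reliable a *mean* score would be if a future study
used ``n_i`` items and ``n_r`` raters.  Each G-study component is divided by
the number of conditions it is averaged over (items for i and p x i, raters
for r and p x r, their product for the two-way i x r and the residual;
persons are the object of measurement and keep divisor 1).  Two error
variances follow:

* relative error  sigma2_delta = s2(pi)/n_i + s2(pr)/n_r + s2(pir,e)/(n_i n_r)
  — the error relevant to rank-order comparisons between persons;
* absolute error  sigma2_Delta = sigma2_delta + s2(i)/n_i + s2(r)/n_r
  + s2(ir)/(n_i n_r) — adds the facet main effects, relevant to
  criterion-referenced decisions.

The generalizability coefficient E-rho2 = s2(p) / (s2(p) + sigma2_delta) is
the G-theory analogue of coefficient alpha; the dependability coefficient
Phi = s2(p) / (s2(p) + sigma2_Delta) is never larger.  0.80 is the
conventional bar for "excellent" on either scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .gstudy import COMPONENT_NAMES, VarianceComponents

__all__ = [
    "DStudyResult",
    "CoefficientCurve",
    "round_half_up",
    "relative_error_variance",
    "absolute_error_variance",
    "generalizability_coefficient",
    "dependability_coefficient",
    "project_components",
    "dstudy_table",
    "coefficient_curve",
    "minimal_design",
    "dstudy_frame",
]

_DIVISOR_FACET = {"p": "one", "i": "i", "r": "r", "pi": "i", "pr": "r", "ri": "ir", "pir_e": "ir"}


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_design(n_i: int, n_r: int) -> None:
    if n_i < 1 or n_r < 1:
        raise ValueError(f"design sizes must be >= 1, got n_i={n_i}, n_r={n_r}")


@dataclass(frozen=True)
class DStudyResult:
    """Projected components, error variances, and coefficients for one design."""

    n_i: int
    n_r: int
    projected: dict[str, float]
    sigma2_delta: float
    sigma2_Delta: float
    e_rho2: float
    phi: float
    label: str = ""


@dataclass(frozen=True)
class CoefficientCurve:
    """A coefficient evaluated along one facet's size, the other held fixed."""

    varying_facet: str  # "items" or "raters"
    fixed_n: int
    which: str  # "e_rho2" or "phi"
    points: list[tuple[int, float]]
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["n", self.which])


def relative_error_variance(vc: VarianceComponents, n_i: int, n_r: int) -> float:
    """sigma2_delta: person-by-facet interactions averaged over the design."""
    _check_design(n_i, n_r)
    return vc.sigma2_pi / n_i + vc.sigma2_pr / n_r + vc.sigma2_pir_e / (n_i * n_r)


def absolute_error_variance(vc: VarianceComponents, n_i: int, n_r: int) -> float:
    """sigma2_Delta: relative error plus facet main effects and i x r."""
    _check_design(n_i, n_r)
    return (
        vc.sigma2_i / n_i
        + vc.sigma2_r / n_r
        + vc.sigma2_pi / n_i
        + vc.sigma2_pr / n_r
        + vc.sigma2_ri / (n_i * n_r)
        + vc.sigma2_pir_e / (n_i * n_r)
    )


def _coefficient(sigma2_p: float, error: float, name: str) -> float:
    if sigma2_p < 0 or error < 0:
        raise ValueError(f"{name}: variances must be non-negative")
    if sigma2_p == 0 and error == 0:
        raise ValueError(f"{name} is undefined when both variances are zero")
    return sigma2_p / (sigma2_p + error)


def generalizability_coefficient(sigma2_p: float, sigma2_delta: float) -> float:
    """E-rho2 = universe-score variance over (itself + relative error)."""
    return _coefficient(sigma2_p, sigma2_delta, "generalizability coefficient")


def dependability_coefficient(sigma2_p: float, sigma2_Delta: float) -> float:
    """Phi = universe-score variance over (itself + absolute error)."""
    return _coefficient(sigma2_p, sigma2_Delta, "dependability coefficient")


def project_components(
    vc: VarianceComponents, n_i: int, n_r: int, printed_table_mode: bool = False
) -> dict[str, float]:
    """Divide each component by its design divisor.

    With ``printed_table_mode`` the projected values are rounded half-up to
    3 decimals, matching how published D-study tables print them (their
    error variances are sums of the printed, rounded components).
    """
    _check_design(n_i, n_r)
    divisors = {"one": 1, "i": n_i, "r": n_r, "ir": n_i * n_r}
    comp = vc.as_dict()
    projected = {name: comp[name] / divisors[_DIVISOR_FACET[name]] for name in COMPONENT_NAMES}
    if printed_table_mode:
        projected = {name: round_half_up(v, 3) for name, v in projected.items()}
    return projected


def dstudy_table(
    vc: VarianceComponents, n_i: int, n_r: int, printed_table_mode: bool = False
) -> DStudyResult:
    """Full D-study for one candidate design.

    Error variances are formed from the projected components (rounded first
    in printed-table mode, full precision otherwise) and the coefficients
    from those error variances.
    """
    proj = project_components(vc, n_i, n_r, printed_table_mode=printed_table_mode)
    sigma2_delta = proj["pi"] + proj["pr"] + proj["pir_e"]
    sigma2_Delta = sigma2_delta + proj["i"] + proj["r"] + proj["ri"]
    return DStudyResult(
        n_i=n_i,
        n_r=n_r,
        projected=proj,
        sigma2_delta=sigma2_delta,
        sigma2_Delta=sigma2_Delta,
        e_rho2=generalizability_coefficient(proj["p"], sigma2_delta),
        phi=dependability_coefficient(proj["p"], sigma2_Delta),
        label=vc.label,
    )


def _design_for(varying: str, n: int, fixed_n: int) -> tuple[int, int]:
    if varying == "items":
        return n, fixed_n
    if varying == "raters":
        return fixed_n, n
    raise ValueError(f"unknown varying facet {varying!r}; expected 'items' or 'raters'")


def coefficient_curve(
    vc: VarianceComponents,
    varying: str,
    fixed_n: int,
    max_n: int = 10,
    which: str = "e_rho2",
) -> CoefficientCurve:
    """Evaluate a coefficient for facet sizes 1..max_n, the other fixed."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    if which not in ("e_rho2", "phi"):
        raise ValueError(f"unknown coefficient {which!r}; expected 'e_rho2' or 'phi'")
    points = []
    for n in range(1, max_n + 1):
        n_i, n_r = _design_for(varying, n, fixed_n)
        result = dstudy_table(vc, n_i, n_r)
        points.append((n, getattr(result, which)))
    return CoefficientCurve(
        varying_facet=varying, fixed_n=fixed_n, which=which, points=points, label=vc.label
    )


def minimal_design(
    vc: VarianceComponents,
    threshold: float = 0.80,
    varying: str = "items",
    fixed_n: int = 3,
    which: str = "e_rho2",
    cap: int = 10,
) -> int | None:
    """Smallest facet size (<= cap) whose coefficient reaches the threshold.

    Integer designs only; returns ``None`` when no size up to ``cap``
    reaches the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    curve = coefficient_curve(vc, varying, fixed_n, max_n=cap, which=which)
    for n, value in curve.points:
        if value >= threshold:
            return n
    return None


def dstudy_frame(result: DStudyResult) -> pd.DataFrame:
    """One-column D-study report: projected components, errors, coefficients.

    Components print at 3 decimals and coefficients at 2 (half-up) in the
    formatted CSV written by the command-line layer.
    """
    rows = [("sigma2_p", 1, result.projected["p"])]
    ns = {"i": result.n_i, "r": result.n_r, "pi": result.n_i, "pr": result.n_r}
    for name in ("r", "i", "pr", "pi", "ri", "pir_e"):
        n = ns.get(name, result.n_i * result.n_r)
        rows.append((f"sigma2_{name}", n, result.projected[name]))
    rows += [
        ("sigma2_delta", None, result.sigma2_delta),
        ("sigma2_Delta", None, result.sigma2_Delta),
        ("e_rho2", None, result.e_rho2),
        ("phi", None, result.phi),
    ]
    return pd.DataFrame(rows, columns=["quantity", "n", "value"])
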