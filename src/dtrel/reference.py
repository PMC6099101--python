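"""Reference variance components from a published layperson-rating G-study.

These are the reported variance-component estimates from a generalizability
study of crowd-sourced (MTurk) creativity ratings of divergent-thinking
responses: 80 persons x 2 items x 3 raters per task family, scored with the
average-rating and snapshot systems.  They serve three purposes here:

* worked D-study examples (the 2-item, 3-rater design and the 1-10 curves);
* generating truth for the parameter-recovery simulations;
* regression anchors in the test suite.

``*_GSTUDY`` sets are the G-study estimates (per single item and rater).
``*_DSTUDY_PROJECTED`` sets are the same study's printed D-study components
for the 2-item, 3-rater design, i.e. already divided by the design divisors
and rounded to 3 decimals as published.  The Consequences person variance
prints as 0.067 in the G-study table but 0.068 in the D-study table of the
source report; each set reproduces its own table.
"""

from __future__ import annotations

from .gstudy import VarianceComponents

__all__ = [
    "AVERAGE_AU_GSTUDY",
    "AVERAGE_CON_GSTUDY",
    "SNAPSHOT_AU_GSTUDY",
    "SNAPSHOT_CON_GSTUDY",
    "AVERAGE_AU_DSTUDY_PROJECTED",
    "AVERAGE_CON_DSTUDY_PROJECTED",
    "SNAPSHOT_AU_DSTUDY_PROJECTED",
    "SNAPSHOT_CON_DSTUDY_PROJECTED",
    "GSTUDY_SETS",
    "DSTUDY_PROJECTED_SETS",
]

# order: p, i, r, pi, pr, ri, pir_e

AVERAGE_AU_GSTUDY = VarianceComponents(
    0.167, 0.069, 0.181, 0.139, 0.008, 0.021, 0.096, label="average/alternative_uses"
)
AVERAGE_CON_GSTUDY = VarianceComponents(
    0.067, 0.000, 0.351, 0.088, 0.015, 0.008, 0.088, label="average/consequences"
)
SNAPSHOT_AU_GSTUDY = VarianceComponents(
    0.098, 0.041, 0.286, 0.000, 0.104, 0.027, 0.971, label="snapshot/alternative_uses"
)
SNAPSHOT_CON_GSTUDY = VarianceComponents(
    0.100, 0.016, 0.161, 0.034, 0.026, 0.000, 1.065, label="snapshot/consequences"
)

# printed D-study components for n_i=2, n_r=3 (divisors already applied)
AVERAGE_AU_DSTUDY_PROJECTED = VarianceComponents(
    0.167, 0.035, 0.060, 0.069, 0.003, 0.004, 0.016, label="average/alternative_uses"
)
AVERAGE_CON_DSTUDY_PROJECTED = VarianceComponents(
    0.068, 0.000, 0.117, 0.044, 0.005, 0.001, 0.015, label="average/consequences"
)
SNAPSHOT_AU_DSTUDY_PROJECTED = VarianceComponents(
    0.098, 0.020, 0.095, 0.000, 0.035, 0.005, 0.162, label="snapshot/alternative_uses"
)
SNAPSHOT_CON_DSTUDY_PROJECTED = VarianceComponents(
    0.100, 0.008, 0.054, 0.017, 0.009, 0.000, 0.117, label="snapshot/consequences"
)

GSTUDY_SETS = {
    ("average", "alternative_uses"): AVERAGE_AU_GSTUDY,
    ("average", "consequences"): AVERAGE_CON_GSTUDY,
    ("snapshot", "alternative_uses"): SNAPSHOT_AU_GSTUDY,
    ("snapshot", "consequences"): SNAPSHOT_CON_GSTUDY,
}

DSTUDY_PROJECTED_SETS = {
    ("average", "alternative_uses"): AVERAGE_AU_DSTUDY_PROJECTED,
    ("average", "consequences"): AVERAGE_CON_DSTUDY_PROJECTED,
    ("snapshot", "alternative_uses"): SNAPSHOT_AU_DSTUDY_PROJECTED,
    ("snapshot", "consequences"): SNAPSHOT_CON_DSTUDY_PROJECTED,
}
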