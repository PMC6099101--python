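"""D-study: error variances, coefficients, curves, and design recommendations.

Two inputs are projected to candidate designs:

* the G-study components estimated from the synthetic data (stage 03);
* the reference published components, in printed-table mode, reproducing
  the worked 2-item x 3-rater example (E-rho2 = 0.65 / Phi = 0.47 for
  average-rated Alternative Uses, 0.52 / 0.27 for Consequences).

Also writes E-rho2 and Phi curves for 1-10 raters (2 items fixed) and 1-10
items (3 raters fixed), and the smallest item count reaching E-rho2 >= 0.80
with 3 raters.

Reads results/gstudy/, writes results/dstudy/.
"""

from pathlib import Path

import pandas as pd

from dtrel import (
    coefficient_curve,
    dstudy_table,
    minimal_design,
    reference,
    write_table,
)
from dtrel.dstudy import dstudy_frame, round_half_up
from dtrel.gstudy import COMPONENT_NAMES, VarianceComponents

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "dstudy"


def load_estimated(system: str, family: str) -> VarianceComponents:
    table = pd.read_csv(ROOT / "gstudy" / f"components_{system}_{family}.csv")
    lookup = dict(zip(table["component"], table["estimate"]))
    return VarianceComponents(
        *[lookup[c] for c in COMPONENT_NAMES], label=f"{system}/{family}"
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for system in ("average", "snapshot"):
        for family in ("alternative_uses", "consequences"):
            for source, vc in (
                ("estimated", load_estimated(system, family)),
                ("reference", reference.GSTUDY_SETS[(system, family)]),
            ):
                printed = source == "reference"
                result = dstudy_table(vc, n_i=2, n_r=3, printed_table_mode=printed)
                write_table(dstudy_frame(result), OUT / f"design_2i_3r_{source}_{system}_{family}.csv")
                if printed:
                    print(
                        f"{system}/{family} (reference, 2 items x 3 raters): "
                        f"E-rho2 = {round_half_up(result.e_rho2, 2):.2f}, "
                        f"Phi = {round_half_up(result.phi, 2):.2f}"
                    )
                for vary, fixed in (("raters", 2), ("items", 3)):
                    for which in ("e_rho2", "phi"):
                        curve = coefficient_curve(vc, vary, fixed_n=fixed, max_n=10, which=which)
                        write_table(
                            curve.as_frame(),
                            OUT / f"curve_{which}_vary_{vary}_{source}_{system}_{family}.csv",
                        )
            n_needed = minimal_design(
                reference.GSTUDY_SETS[(system, family)],
                threshold=0.80,
                varying="items",
                fixed_n=3,
            )
            if n_needed:
                print(f"{system}/{family}: E-rho2 >= 0.80 with 3 raters needs {n_needed} items")
            else:
                print(f"{system}/{family}: E-rho2 >= 0.80 not reachable with 3 raters and <= 10 items")
    print(f"D-study tables and curves -> {OUT}")


if __name__ == "__main__":
    main()
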