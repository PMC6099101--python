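"""Build the three scoring systems from the simulated ratings.

Average-rating scores collapse each rater's response ratings to one mean per
(person, item, rater); snapshot tables are validated as-is; fluency counts
responses per (person, item).  Per-item composites (mean over raters) feed
the validity stage.

Reads results/data/, writes results/scores/.
"""

from pathlib import Path

import pandas as pd

from dtrel import (
    average_rating_scores,
    composite_scores,
    fluency_scores,
    load_ratings,
    snapshot_scores,
    write_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "scores"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    composites = []
    for family in ("alternative_uses", "consequences"):
        responses = load_ratings(ROOT / "data" / f"responses_{family}.csv")
        average = average_rating_scores(responses)
        fluency = fluency_scores(responses)
        snapshot = snapshot_scores(load_ratings(ROOT / "data" / f"snapshot_{family}.csv", layout="score_level"))
        write_table(average, OUT / f"average_{family}.csv")
        write_table(fluency, OUT / f"fluency_{family}.csv")
        write_table(snapshot, OUT / f"snapshot_{family}.csv")
        composites.append(composite_scores(scores=average, fluency=fluency, system="average"))
        composites.append(composite_scores(scores=snapshot, system="snapshot"))
        print(
            f"{family}: average scores in "
            f"[{average['score'].min():.2f}, {average['score'].max():.2f}], "
            f"mean fluency {fluency['fluency'].mean():.2f}"
        )
    write_table(pd.concat(composites, ignore_index=True), OUT / "composites_per_item.csv")
    print(f"per-item composites for validity -> {OUT / 'composites_per_item.csv'}")


if __name__ == "__main__":
    main()
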