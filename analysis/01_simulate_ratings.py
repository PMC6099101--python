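"""Generate the synthetic study data every later stage consumes.

Emulates the study conditions: 80 persons, two task families with two items
each, three raters, an average of ~6.5 responses per person per item.
Response-level tables (for the average-rating system) use the reference
average-rating G-study components as generating truth; snapshot tables are
drawn directly at score level from the snapshot components, discretized to
the integer 1-5 scale as snapshot raters would produce.

Writes results/data/responses_<family>.csv and snapshot_<family>.csv.
"""

from pathlib import Path

from dtrel import reference, write_table
from dtrel.simulate import SimulationSpec, simulate_response_level, simulate_scores

SEED = 20180813
ITEMS = {"alternative_uses": ["brick", "knife"], "consequences": ["sleep", "inches"]}

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def relabel_items(table, family):
    generated = sorted(table["item_id"].unique())
    return table.assign(item_id=table["item_id"].map(dict(zip(generated, ITEMS[family]))))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for offset, family in enumerate(sorted(ITEMS)):
        responses = simulate_response_level(
            SimulationSpec(
                true_components=reference.GSTUDY_SETS[("average", family)],
                n_p=80,
                n_i=2,
                n_r=3,
                fluency_mean=6.5,
                family=family,
                seed=SEED + offset,
            )
        )
        responses = relabel_items(responses, family)
        write_table(responses, OUT / f"responses_{family}.csv")
        snapshot = simulate_scores(
            SimulationSpec(
                true_components=reference.GSTUDY_SETS[("snapshot", family)],
                n_p=80,
                n_i=2,
                n_r=3,
                family=family,
                discretize=True,
                seed=SEED + 10 + offset,
            )
        )
        snapshot = relabel_items(snapshot, family)
        write_table(snapshot, OUT / f"snapshot_{family}.csv")
        n_resp = responses.groupby(["person_id", "item_id"])["response_id"].nunique().sum()
        print(
            f"{family}: {n_resp} unique responses, {len(responses)} rating rows, "
            f"{len(snapshot)} snapshot scores -> {OUT}"
        )


if __name__ == "__main__":
    main()
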