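import numpy as np
import pandas as pd
import pytest

from dtrel.gstudy import VarianceComponents
from dtrel.simulate import SimulationSpec, simulate_scores


def make_response_df(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "family", "item_id", "rater_id", "response_id", "rating"]
    )


def make_score_df(rows):
    return pd.DataFrame(rows, columns=["person_id", "family", "item_id", "rater_id", "score"])


def full_grid_scores(n_p, n_i, n_r, values, family="alternative_uses"):
    """Score table over a complete p x i x r grid, values in C order."""
    arr = np.asarray(values, dtype=float).reshape(n_p, n_i, n_r)
    rows = []
    for p in range(n_p):
        for i in range(n_i):
            for r in range(n_r):
                rows.append((f"p{p + 1}", family, f"item{i + 1}", f"rater{r + 1}", arr[p, i, r]))
    return make_score_df(rows)


@pytest.fixture
def au_components():
    """Reference average-rating Alternative Uses G-study components."""
    return VarianceComponents(0.167, 0.069, 0.181, 0.139, 0.008, 0.021, 0.096)


@pytest.fixture
def study_sized_scores():
    """Balanced synthetic 80 x 2 x 3 score table at the study conditions."""
    return simulate_scores(SimulationSpec(seed=20180813))


@pytest.fixture
def small_responses():
    """2 persons x 1 item x 2 raters x 3 responses, hand-written ratings."""
    rows = []
    ratings = {
        ("p1", "raterA"): [1, 2, 3],
        ("p1", "raterB"): [2, 2, 5],
        ("p2", "raterA"): [4, 4, 1],
        ("p2", "raterB"): [5, 3, 3],
    }
    for (person, rater), vals in ratings.items():
        for k, v in enumerate(vals):
            rows.append((person, "alternative_uses", "brick", rater, f"resp{k + 1}", v))
    return make_response_df(rows)
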