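"""Variance-component estimation: ANOVA identities, EMS algebra, oracles."""

import subprocess
import textwrap

import numpy as np
import pytest

from dtrel.data_model import RatingValidationError
from dtrel.gstudy import (
    COMPONENT_NAMES,
    estimate_variance_components,
    gstudy,
    mean_squares,
    mean_squares_array,
    percent_variance,
)
from dtrel.simulate import SimulationSpec, simulate_scores

from conftest import full_grid_scores


def brute_force_sums_of_squares(x):
    """Triple-loop evaluation of the defining SS deviations (oracle)."""
    n_p, n_i, n_r = x.shape
    g = x.mean()
    ss = dict.fromkeys(["p", "i", "r", "pi", "pr", "ir", "pir", "total"], 0.0)
    for p in range(n_p):
        for i in range(n_i):
            for r in range(n_r):
                mp, mi, mr = x[p].mean(), x[:, i].mean(), x[:, :, r].mean()
                mpi, mpr, mir = x[p, i].mean(), x[p, :, r].mean(), x[:, i, r].mean()
                ss["p"] += (mp - g) ** 2
                ss["i"] += (mi - g) ** 2
                ss["r"] += (mr - g) ** 2
                ss["pi"] += (mpi - mp - mi + g) ** 2
                ss["pr"] += (mpr - mp - mr + g) ** 2
                ss["ir"] += (mir - mi - mr + g) ** 2
                ss["pir"] += (x[p, i, r] - mpi - mpr - mir + mp + mi + mr - g) ** 2
                ss["total"] += (x[p, i, r] - g) ** 2
    return ss


def ems_matrix_solve(ms):
    """Numeric solve of the 7x7 expected-mean-squares system (oracle)."""
    n_p, n_i, n_r = ms.design.n_p, ms.design.n_i, ms.design.n_r
    effects = ["p", "i", "r", "pi", "pr", "ir", "pir"]
    comps = ["p", "i", "r", "pi", "pr", "ri", "pir_e"]
    coef = {
        "p": {"p": n_i * n_r, "pi": n_r, "pr": n_i, "pir_e": 1},
        "i": {"i": n_p * n_r, "pi": n_r, "ri": n_p, "pir_e": 1},
        "r": {"r": n_p * n_i, "pr": n_i, "ri": n_p, "pir_e": 1},
        "pi": {"pi": n_r, "pir_e": 1},
        "pr": {"pr": n_i, "pir_e": 1},
        "ir": {"ri": n_p, "pir_e": 1},
        "pir": {"pir_e": 1},
    }
    A = np.array([[coef[e].get(c, 0.0) for c in comps] for e in effects])
    b = np.array([ms[e] for e in effects])
    return dict(zip(comps, np.linalg.solve(A, b)))


def test_constant_table_has_zero_mean_squares():
    ms = mean_squares(full_grid_scores(2, 2, 2, np.full(8, 3.0)))
    assert all(v == 0.0 for v in ms.ms.values())


def test_sums_of_squares_match_brute_force_oracle():
    x = np.arange(8, dtype=float).reshape(2, 2, 2) ** 1.5  # asymmetric hand grid
    ms = mean_squares_array(x)
    oracle = brute_force_sums_of_squares(x)
    for eff in ("p", "i", "r", "pi", "pr", "ir", "pir"):
        assert ms[eff] * ms.df[eff] == pytest.approx(oracle[eff], rel=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_anova_identity_on_random_grids(seed):
    rng = np.random.default_rng(seed)
    shape = rng.integers(2, 6, size=3)
    x = rng.normal(3, 1, size=shape)
    ms = mean_squares_array(x)
    total = np.sum((x - x.mean()) ** 2)
    effect_sum = sum(ms[e] * ms.df[e] for e in ms.ms)
    assert effect_sum == pytest.approx(total, rel=1e-9)


def test_equal_mean_squares_leave_only_residual():
    ms = mean_squares_array(np.zeros((3, 3, 3)))
    ms.ms.update(dict.fromkeys(ms.ms, 2.5))
    vc = estimate_variance_components(ms)
    assert vc.sigma2_pir_e == 2.5
    for name in COMPONENT_NAMES[:-1]:
        assert getattr(vc, "sigma2_" + name) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_closed_form_matches_numeric_ems_solve(seed):
    rng = np.random.default_rng(100 + seed)
    x = rng.normal(3, 1, size=(3, 3, 3))
    ms = mean_squares_array(x)
    numeric = ems_matrix_solve(ms)
    vc = estimate_variance_components(ms)
    for name in COMPONENT_NAMES:
        assert vc.raw[name] == pytest.approx(numeric[name], abs=1e-9)


def test_negative_solutions_truncated_but_raw_kept():
    # pure noise on a tiny grid practically guarantees a negative solution
    for seed in range(20):
        x = np.random.default_rng(seed).normal(0, 1, size=(3, 2, 2))
        vc = estimate_variance_components(mean_squares_array(x))
        if any(v < 0 for v in vc.raw.values()):
            break
    else:
        pytest.fail("no negative raw estimate found")
    assert all(v >= 0 for v in vc.as_dict().values())
    for name in COMPONENT_NAMES:
        assert vc.as_dict()[name] == max(0.0, vc.raw[name])


class TestInvariances:
    def test_relabeling_does_not_change_estimates(self, study_sized_scores):
        vc = gstudy(study_sized_scores)
        relabeled = study_sized_scores.copy()
        relabeled["person_id"] = "z_" + relabeled["person_id"]
        relabeled["rater_id"] = relabeled["rater_id"].map(
            {"rater1": "carol", "rater2": "alice", "rater3": "bob"}
        )
        vc2 = gstudy(relabeled)
        for name in COMPONENT_NAMES:
            assert vc2.as_dict()[name] == pytest.approx(vc.as_dict()[name], abs=1e-12)

    def test_shift_invariance_and_quadratic_scaling(self, study_sized_scores):
        vc = gstudy(study_sized_scores)
        shifted = study_sized_scores.assign(score=study_sized_scores.score + 0.7)
        scaled = study_sized_scores.assign(score=study_sized_scores.score * 2.0)
        for name, value in gstudy(shifted).as_dict().items():
            assert value == pytest.approx(vc.as_dict()[name], abs=1e-10)
        for name, value in gstudy(scaled).as_dict().items():
            assert value == pytest.approx(4.0 * vc.as_dict()[name], rel=1e-9)


class TestRefusals:
    def test_unbalanced_table_refused(self, study_sized_scores):
        with pytest.raises(RatingValidationError, match="balanced"):
            gstudy(study_sized_scores.iloc[:-1])

    def test_single_level_facet_refused(self):
        scores = full_grid_scores(3, 1, 3, np.arange(9))
        with pytest.raises(RatingValidationError, match=">= 2"):
            gstudy(scores)


class TestPercentVariance:
    def test_symmetric_split(self):
        from dtrel.gstudy import VarianceComponents

        vc = VarianceComponents(1, 0, 0, 0, 0, 0, 1)
        pct = percent_variance(vc)
        assert pct["p"] == 50.0
        assert pct["pir_e"] == 50.0
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        from dtrel.gstudy import VarianceComponents

        with pytest.raises(RatingValidationError):
            percent_variance(VarianceComponents(0, 0, 0, 0, 0, 0, 0))


def test_ems_agrees_with_reml_on_interior_data(tmp_path):
    """Cross-check against lme4's REML fit of the crossed random model.

    For balanced designs whose component solutions are strictly positive,
    REML and the closed-form ANOVA estimator coincide; components are made
    large so the fit stays off the boundary.
    """
    from dtrel.gstudy import VarianceComponents

    truth = VarianceComponents(0.5, 0.4, 0.45, 0.35, 0.3, 0.4, 0.5)
    scores = simulate_scores(SimulationSpec(true_components=truth, n_p=40, n_i=4, n_r=4, seed=11))
    csv_path = tmp_path / "scores.csv"
    scores.to_csv(csv_path, index=False)
    r_code = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv_path}")
        fit <- lmer(score ~ 1 + (1|person_id) + (1|item_id) + (1|rater_id) +
                    (1|person_id:item_id) + (1|person_id:rater_id) +
                    (1|item_id:rater_id), data = d,
                    control = lmerControl(check.nobs.vs.nlev = "ignore",
                                          check.nobs.vs.nRE = "ignore"))
        v <- as.data.frame(VarCorr(fit))
        v <- v[, c("grp", "vcov")]
        write.csv(v, "{tmp_path / 'vc.csv'}", row.names = FALSE)
        """
    )
    script = tmp_path / "fit.R"
    script.write_text(r_code)
    proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    import pandas as pd

    reml = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
    vc = gstudy(scores)
    mapping = {
        "person_id": "p",
        "item_id": "i",
        "rater_id": "r",
        "person_id:item_id": "pi",
        "person_id:rater_id": "pr",
        "item_id:rater_id": "ri",
        "Residual": "pir_e",
    }
    for grp, name in mapping.items():
        assert reml[grp] == pytest.approx(vc.as_dict()[name], abs=2e-4), name
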