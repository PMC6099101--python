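# dtrel — how dependable are subjective creativity ratings?

`dtrel` is an analysis package for researchers who collect divergent-thinking
data (Alternative Uses and Consequences prompts), have the responses rated on
a 1–5 scale by a panel of raters, and need to know how many raters and items
a reliable study actually requires.  It implements the full generalizability-
theory workflow for the fully crossed **person × item × rater** design:

* **Scoring** — the *average-rating* system (every response rated, then
  averaged per rater per item), the *snapshot* system (one holistic rating
  per response set), and *fluency* (response counts).
* **G-study** — closed-form expected-mean-squares estimation of the seven
  variance components σ²(p), σ²(i), σ²(r), σ²(pi), σ²(pr), σ²(ri),
  σ²(pir,e) from a balanced score table, with percent-of-variance reporting.
* **D-study** — projection of those components to any candidate design
  (nᵢ items, nᵣ raters):

  σ²δ = σ²(pi)/nᵢ + σ²(pr)/nᵣ + σ²(pir,e)/(nᵢnᵣ)   (relative error)

  σ²Δ = σ²δ + σ²(i)/nᵢ + σ²(r)/nᵣ + σ²(ri)/(nᵢnᵣ)   (absolute error)

  𝔼ρ² = σ²(p)/(σ²(p)+σ²δ)  and  Φ = σ²(p)/(σ²(p)+σ²Δ),

  plus coefficient curves over 1–10 raters/items and minimal-design search
  (𝔼ρ² ≥ 0.80 is the conventional bar).
* **Validity descriptives** — means, SDs, and the Pearson correlation matrix
  across scoring systems and fluency.
* **Simulation** — a crossed random-effects generator
  (X_pir = μ + ν_p + ν_i + ν_r + ν_pi + ν_pr + ν_ir + ε_pir) at score and
  response level, so the entire pipeline is testable without external data,
  plus Monte-Carlo parameter-recovery summaries.

Task family (Alternative Uses vs. Consequences) is treated as a fixed
partition: every analysis runs separately within each family.

## Worked example

The package ships reference variance components from a published layperson
(MTurk) rating study of 80 persons × 2 items × 3 raters per family.
Projecting the average-rating Alternative Uses components to that same
design:

```python
>>> from dtrel import reference, dstudy_table
>>> from dtrel.dstudy import round_half_up
>>> res = dstudy_table(reference.AVERAGE_AU_GSTUDY, n_i=2, n_r=3,
...                    printed_table_mode=True)
>>> round(res.sigma2_delta, 3), round(res.sigma2_Delta, 3)
(0.089, 0.188)
>>> round_half_up(res.e_rho2, 2), round_half_up(res.phi, 2)
(0.65, 0.47)
```

𝔼ρ² = 0.65 says that under a 2-item, 3-rater design only 65% of the
variance in persons' mean scores is universe-score (true) variance for
rank-order decisions — short of the 0.80 bar — and the dependability Φ = 0.47
is lower still because rater main effects are large.  Asking how many
Alternative Uses items would be enough with 3 raters:

```python
>>> from dtrel import minimal_design
>>> minimal_design(reference.AVERAGE_AU_GSTUDY, threshold=0.80,
...                varying="items", fixed_n=3)
5
```

## The analysis pipeline

Numbered drivers under `analysis/` rerun the whole study on synthetic data
at the study's dimensions, writing tables under `results/`:

```sh
python analysis/01_simulate_ratings.py    # crossed ratings, both families
python analysis/02_build_scores.py        # average / snapshot / fluency
python analysis/03_gstudy_components.py   # seven components + % variance
python analysis/04_dstudy_projections.py  # coefficients, curves, recommendations
python analysis/05_validity_correlations.py
python analysis/06_parameter_recovery.py  # estimator calibration
```

The same stages are available as subcommands of the `dtrel` console script
(`simulate`, `score`, `gstudy`, `dstudy`, `curves`, `recommend`, `validity`,
`run`); `dtrel run --config cfg.yaml` executes the pipeline end to end with
one seed and writes a reproducibility log.

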