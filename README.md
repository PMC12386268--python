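# halffield

Analysis pipeline for **half-field irradiation cell-migration experiments**,
in which half of a 60 mm culture dish is shielded with lead during X-ray
exposure so that directly irradiated (*In-field*) and shielded
(*Out-of-field*) cells share one dish.  Comparing their migration against
sham-irradiated (*Control*) and fully irradiated (*Uniform*) dishes isolates
radiation-induced *bystander* effects on cell motility — changes in cells
that were never traversed by the beam.  The package is aimed at
radiation-biology and cell-migration researchers who want a tested,
reproducible reference implementation of this analysis, together with a
calibrated synthetic-data generator for validating trackers and statistics.

## What it computes

Cells are tracked over 24 h of time-lapse imaging at 15 min intervals
(97 frames).  For each cell *i* with positions `x_i(t)`:

- **velocity** `v_i = (Σ_t ‖x_i(t+Δt) − x_i(t)‖) / T` (total path length over
  elapsed time, μm/h),
- **total distance** `Σ_t ‖x_i(t+Δt) − x_i(t)‖` (μm),
- **net displacement** `‖x_i(T) − x_i(0)‖` (μm),
- the **ensemble mean squared displacement**

  `MSD(t) = (1/N) Σ_i ‖x_i(t) − x_i(0)‖²`,

  with an ordinary least-squares linear fit `MSD ≈ a + b·t`; linear growth
  (high R²) is the signature of random-walk (diffusive) migration.

Group comparisons use **Steel's many-to-one rank test**: each treatment
group is compared with the shared control by a standardized mid-rank
Wilcoxon statistic `Z_g`, and the familywise two-sided adjusted p-value is
`P(max_j |Z_j| ≥ |z_g|)` under the joint null.  Because all comparisons
share the control sample the statistics follow a one-factor correlation
structure `corr(Z_g, Z_h) = √(n_g/(n_g+n_0)) · √(n_h/(n_h+n_0))`, which the
package exploits to evaluate the max-|Z| tail by a single deterministic
Gaussian quadrature (a sampled/enumerated permutation mode is also
provided).  Cell-cycle (FUCCI reporter) distributions — G1 red, early-S
yellow, S/G2/M green — are compared by a Pearson chi-square test of
homogeneity.

Cells inside a 20 mm-wide exclusion band straddling the shield edge (steep
dose penumbra) are excluded, as are incomplete, field-exiting and
non-motile tracks.  A normal-CDF penumbra model
`D(x) = D₀ · Φ((x_b − x)/σ_p)` describes the lateral dose falloff.

The synthetic generator draws per-cell speeds from a lognormal law whose
median and log-sigma are calibrated to published group median/IQR
velocities (presets `fig2-*` for radiation alone, `fig4-*` for
cisplatin + radiation, named after the source figures), and realises them
as random walks with optional directional persistence.  A cisplatin FUCCI
preset arrests ≈70.3 % of cells in the green S/G2/M state.

## Worked example

Run the radiation-alone experiment end to end (four groups of 1500
synthetic cells, tracked, filtered, measured and tested):

```python
from halffield import preset_config, run_experiment

record = run_experiment(preset_config("fig2", n_cells_per_group=1500, seed=42),
                        "out/fig2")
print(record.stage_counts)   # {'generated': 6000, 'kept': 5999,
                             #  'rejected': 1, 'metrics_rows': 5999}
```

`out/fig2/stats.json` then contains, for migration velocity (μm/h):

| group        | n    | median | IQR         | z (vs control) | adjusted p |
|--------------|------|--------|-------------|----------------|------------|
| control      | 1499 | 5.64   | 3.36 – 9.25 | —              | —          |
| uniform      | 1500 | 4.99   | 2.99 – 8.24 | −4.67          | 9.0e-06    |
| in-field     | 1500 | 5.69   | 3.44 – 9.73 | +0.45          | 0.94       |
| out-of-field | 1500 | 4.71   | 2.73 – 8.09 | −6.21          | 1.5e-09    |

i.e. the Uniform and Out-of-field groups are significantly *slower* than
Control while the In-field group is not — the bystander-suppression
signature this experimental design probes.  The ensemble MSD fit for the
control group reports `slope 27.9 μm²/h, R² 0.993,
RANDOM_WALK_CONSISTENT`, and the FUCCI chi-square block compares the
control and cisplatin cell-cycle distributions (here χ² = 183.2, df = 2,
p = 1.7e-40).  Negative `z` means slower than control.

The same stages are available as a CLI:

```sh
halffield simulate --config fig2 --n-cells 200 --seed 1 --out tracks.csv
halffield track    --labels movie.tif --pixel-size 1.3 --max-step 30 --out tracks.csv
halffield metrics  --tracks tracks.csv --out metrics.csv
halffield stats    --metrics metrics.csv --out stats.json
halffield run      --config fig4 --out-dir out/fig4
halffield validate --config myconfig.yaml
```

## Layout

- `src/halffield/geometry.py` — dish/shield geometry, region labels, dose model
- `src/halffield/synthetic.py` — calibrated trajectory/FUCCI generator, label-movie renderer
- `src/halffield/tracking.py` — centroid detection, greedy gated linking, inclusion filters
- `src/halffield/metrics.py` — velocity, distances, ensemble MSD + linear fit
- `src/halffield/stats.py` — Steel's test, chi-square, median/IQR summaries
- `src/halffield/pipeline.py`, `cli.py` — orchestration, config, run records
- `docs/methods.md` — model assumptions, parameter choices, limitations
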