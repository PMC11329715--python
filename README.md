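# vipertherm

Thermal-ecology analysis of a cold-adapted alpine viper (*Vipera graeca*,
an endangered snake of subalpine meadows in the Pindos range), built as a
reusable, fully tested pipeline.  It is aimed at herpetologists and thermal
ecologists who want the standard thermoregulation-index workflow — from raw
thermal-gradient trials and field temperature loggers to climate-scenario
activity budgets — as seeded, reproducible Python rather than a one-off
analysis script.

## What it computes

**Set-point estimation.**  For each individual, a Gaussian-kernel density is
fitted to the body temperatures selected in a laboratory thermal gradient,
rescaled to [0, 1] and evaluated on a fixed grid (15–45 °C in 0.05 °C
steps).  The preferred temperature *T*<sub>p</sub> is the grid temperature
at the peak; the set-point range *T*<sub>set</sub> spans the outermost
half-maximum crossings.

**Thermoregulation indices** (Hertz et al. conventions), per population:

- accuracy  *d*<sub>b</sub> = mean deviation of field body temperature
  *T*<sub>b</sub> from *T*<sub>set</sub> (0 = perfectly accurate);
- habitat thermal quality  *d*<sub>e</sub> = mean deviation of operative
  temperature *T*<sub>e</sub> from *T*<sub>set</sub> over the diurnal
  window 06:00–20:00;
- effectiveness  *E* = 1 − *d*<sub>b</sub>/*d*<sub>e</sub>  and
  *I* = *d*<sub>e</sub> − *d*<sub>b</sub>;
- exploitation  *E*<sub>x</sub> = (records with *T*<sub>b</sub> in
  *T*<sub>set</sub>) / (records whose time-matched *T*<sub>e</sub> overlaps
  *T*<sub>set</sub>), unclamped, so values above 1 are meaningful.

*d*<sub>b</sub> and *d*<sub>e</sub> carry percentile-bootstrap 95% CIs.

**Activity restriction budget.**  Hourly operative temperature over a
365-day year is synthesized per occurrence cell from 12 monthly mean air
temperatures (month-midpoint interpolation + diurnal sinusoid + daylight
radiative gain); the restriction time *h*<sub>r</sub> counts the hours per
year that *T*<sub>e</sub> exceeds the upper *T*<sub>set</sub> bound, under
the current climate and under 3 GCM × 2 SSP warming offsets.

**Phylogenetic signal.**  Blomberg's *K* (permutation test) and Pagel's λ
(maximum likelihood, LR test, upper bound from positive-definiteness so
λ > 1 is reachable) on population *T*<sub>p</sub> over a newick tree with
Grafen branch lengths.

**Population statistics.**  OLS fits (size, latitude), Wilcoxon rank-sum
tests (sex, gravidity, scenarios; exact for small tie-free samples), and
Holm-adjusted pairwise population contrasts.

A seeded synthetic-data generator (`vipertherm.synthgen`) emulates all five
input tables with the study's statistical structure, so the entire pipeline
runs and is tested without any field data.

## Worked example

```bash
python analysis/01_generate_data.py --seed 1
python analysis/02_estimate_tset.py
python analysis/03_thermoregulation_indices.py
python analysis/04_activity_budget.py
python analysis/05_phylogenetic_signal.py
python analysis/06_population_stats.py
```

The second step prints the population-level estimates (°C):

```
population   t_p  t_set_lower  t_set_upper  n_obs
        KU 28.45        25.85        31.70     65
        LA 29.80        26.25        33.05     39
        TO 29.90        27.25        32.50    247
        TY 28.80        25.80        30.90    403
        VA 27.45        24.35        29.55    195

overall mean individual T_p: 28.63 ± 0.21 °C (mean ± SE, n = 73)
```

so the southernmost population (VA) prefers the lowest temperatures and the
northern ones the highest — the latitude trend built into the generator.
The index step then reports, e.g. for TO, *d*<sub>b</sub> = 0.32 (high
accuracy), *d*<sub>e</sub> = 4.46 (a thermally demanding habitat), hence
*E* = 0.93 and *I* = 4.14 — careful, effective thermoregulation — and
flags *d*<sub>b</sub>/*E*/*I* as missing for VA, which has no
body-temperature records.  The budget step prints the scenario summary:

```
scenario  mean_h_r  se_h_r  mean_delta  n_cells
SSP1-2.6     378.5    15.2       305.4      102
SSP5-8.5     866.8    16.9       793.6      102
 current      73.1     9.1         0.0      102

SSP5-8.5 vs SSP1-2.6 rank-sum: W = 10288, P = 1.7e-33
latitude trend of current h_r: b = -111.9 h/degree, P = 2.1e-22
```

i.e. annual restriction time grows sharply under warming, more under the
pessimistic scenario, and decreases with latitude.  The final steps find a
positive female size effect on *T*<sub>p</sub> (b = 0.024 °C/mm,
P = 0.001), a positive latitude effect (b = 1.305 °C/degree), no sex or
gravidity effect, and no phylogenetic signal (*K* = 0.75, P = 0.51;
λ = 0, P = 1) — with the caveat that five tips give these tests very
little power.

The same pipeline runs as one call (`vipertherm.pipeline.run_pipeline`),
accepts user-supplied CSVs in place of any generated table, and is
byte-identical when rerun under the same seed.

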