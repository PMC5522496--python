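# nbslmap

Statistics of the natural blind spot location (NBSL) in standard automated
perimetry, and its effect on pointwise visual-field sensitivity.

The physiological blind spot — the projection of the optic disc — is
located by the Humphrey Field Analyzer at the start of every 24-2 visual
field test and reported at 1-degree resolution relative to fixation. Its
position varies between eyes, tracks refractive error (more myopic eyes
have more eccentric blind spots), and systematically shifts pattern
deviation (PD) values across the field. `nbslmap` reimplements that
analysis as a tested pipeline for researchers in visual psychophysics and
glaucoma diagnostics:

* cohort filters (reliability, recency, clinical normality, removal of the
  perimeter's default blind-spot code, one eye per patient);
* a frequency table of NBSL per 1-degree cell, with count-weighted
  marginals and weighted medians of blind-spot distance and polar angle;
* a Gaussian-process estimate of the continuous NBSL frequency surface
  with the anisotropic squared-exponential kernel
  `k(x_i, x_j) = sigma_f^2 exp(-[(dh/gamma_h)^2 + (dv/gamma_v)^2])`,
  including marginal-likelihood grid search for the hyperparameters;
* median-split PD difference maps with per-location t-tests,
  Benjamini-Hochberg FDR correction, and the average difference for
  significant points (ADSP);
* per-location multiple regression of PD on NBSL distance/angle and
  fixation-loss rate, separating genuine blind-spot effects from the
  fixation-loss confound;
* a seeded synthetic-cohort generator calibrated to the reported cohort
  (11,449 eyes; horizontal NBSL 14.35 +/- 1.36 deg, vertical
  -2.06 +/- 1.28 deg, r = -0.14 between NBSL distance and spherical
  equivalent), so every record-level analysis is testable without
  clinical data.

The frequency table of the 11,449-eye reference cohort ships with the
package (`nbslmap/data/table1_nbsl_counts.csv`); raw per-eye clinical
records are not redistributable, and analyses that need them run on
synthetic cohorts.

## Worked example

Reference-table statistics and the GP surface (deterministic, seconds):

```sh
nbslmap distribution --report stats.json
```

```
total_eyes = 11449
max_count = 1021            at cell (14, -1)
horizontal_mean = 14.348    horizontal_sd = 1.364
vertical_mean = -2.060      vertical_sd = 1.276
median_distance = 14.318    median_angle = -8.130
gp_default_cell = 932.3     # predictive mean at the held-out (15, -1)
surface_max = 1193.5        at (14.4, -1.3) on the 0.1-degree grid
```

The observed frequency peaks at 1021 eyes one degree nasal to the expected
default position; the GP fills the held-out default cell with ~932 eyes
and places the continuous maximum of ~1194 eyes at (14.4, -1.3) — the
blind spot of the average eye sits closer to fixation and slightly lower
than the perimeter's assumed (15, -1).

End-to-end on a calibrated synthetic cohort (simulate, filter, surface,
difference and regression maps, summary JSON):

```sh
nbslmap report --n 11449 --seed 20170721 --outdir out/
```

From `out/summary.json` (this exact run): the distance/refraction
correlation is r = -0.146 (p < 1e-54); splitting eyes at the median NBSL
distance (14.32 deg) gives 29 significant locations with ADSP -0.184 dB
where PD decreases and +0.186 dB where it increases; the regression maps
attribute broad negative effects to fixation loss (48 of 52 locations)
while the distance family retains 25. The numbers match the generator's
planted effect structure — on real data they quantify how far the blind
spot shifts measured sensitivity.

In Python:

```python
import nbslmap as nm

table = nm.load_reference_table()
dense = nm.exclude_sparse_cells(table)          # drop cells with < 5 eyes
model = nm.gp_fit(dense, nm.table1_hyperparams())
surface = nm.gp_surface(model, resolution=0.1)
print(surface.argmax)                           # (14.4, -1.3, 1193.5)
print(nm.marginal_stats(table, "horizontal"))   # mean=14.348, sd=1.364, n=11449
```

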