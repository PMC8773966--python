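# spectsuv

Quantitative analysis of bone SPECT-CT for discriminating metastatic from
degenerative skeletal lesions.

On a whole-body bone scan with ⁹⁹ᵐTc-HDP, both metastases and benign
degenerative changes (facet arthropathy, osteophytes) light up, and telling
them apart visually is a recurring clinical problem in breast-cancer
staging and follow-up. Quantitative SPECT-CT turns the reconstructed
activity map into standardized uptake values, and the hottest-voxel value
of each lesion (SUVmax, normalized by lean body mass) separates the two
lesion populations well enough to support a diagnostic threshold.

`spectsuv` implements that analysis chain as a reusable, tested pipeline
for physicists and imaging researchers:

* **quantification** — decay-corrected actual activity, James lean body
  mass, voxelwise SUVlbm conversion of activity volumes (Bq/mL → g/mL);
* **segmentation** — iterative "global maximum" lesion extraction: pick
  the hottest voxel, grow a fixed-fraction-threshold VOI, exclude, repeat
  (up to five lesions per category);
* **cohort statistics** — Shapiro–Wilk, Mann–Whitney U, empirical ROC with
  the U-statistic identity AUC = U/(n₁n₂), DeLong 95% CI, Youden-optimal
  cut-off under the strict "positive if SUVmax > t" rule, overlap and bin
  breakdowns;
* **synthetic data** — truncated-lognormal SUVmax generators calibrated by
  moment matching to published per-category summaries, whole-cohort
  simulation (70 patients, 236 metastatic / 179 degenerative lesions), and
  digital sphere phantoms with optional blur and Poisson noise for
  end-to-end validation.

## The quantities computed

For a patient with syringe activity $A_{pre}$ assayed at $t_{meas}$,
injection at $t_{adm}$, residual $A_{post}$ assayed at $t_{post}$ and scan
at $t_{scan}$, with λ = 0.693 / T½ (T½ = 6.0067 h for ⁹⁹ᵐTc):

$$A_{actual} = e^{\lambda (t_{adm}-t_{scan})}\; e^{\lambda (t_{meas}-t_{adm})}\,\bigl(A_{pre} - e^{\lambda (t_{post}-t_{meas})} A_{post}\bigr)$$

$$\mathrm{LBM} = \begin{cases}1.07\,W - 148\,(W/H)^2 & \text{female}\\ 1.10\,W - 120\,(W/H)^2 & \text{male}\end{cases} \qquad
\mathrm{SUV_{lbm}} = \frac{C\ [\mathrm{Bq/mL}]\cdot \mathrm{LBM}\ [\mathrm{kg}]\cdot 1000}{A_{actual}\ [\mathrm{Bq}]}\ \ \mathrm{g/mL}$$

The cohort stage tests whether metastatic SUVmax exceeds degenerative
SUVmax (Mann–Whitney), quantifies discrimination (AUC with DeLong CI), and
reports the threshold maximizing Youden's J = sensitivity + specificity − 1.

## Worked example

```sh
spectsuv simulate-cohort --seed 1 --out demo
spectsuv analyze --table demo/lesions.csv --seed 1 --out demo/report.json
spectsuv report --report demo/report.json
```

prints (abridged):

```
| category     | n   | min   | max    | mean  | sd    |
| metastatic   | 236 | 11.19 | 115.17 | 33.29 | 16.53 |
| degenerative | 179 |  3.88 |  25.40 | 10.39 |  4.76 |

- Mann-Whitney U = 40828.5, two-sided p = 1.28e-59
- AUC = 0.966 (95% CI 0.953-0.980)
- Youden cut-off: SUVmax > 16.90 g/mL (sensitivity 89.0%, specificity 89.4%)
- degenerative bins <20 / 20-27 / >=27 g/mL: 172 (96.1%) / 7 (3.9%) / 0 (0.0%)
```

The simulated metastatic lesions (mean 33.29 g/mL) sit far above the
degenerative ones (10.39 g/mL); the difference is overwhelmingly
significant, discrimination is excellent (AUC 0.966), and the optimal
SUVmax threshold lands near 17 g/mL — a lesion hotter than that is almost
certainly metastatic, while the two populations overlap in the 11–25 g/mL
band where the bin breakdown shows 96.1% of degenerative lesions staying
below 20 g/mL.

The same statistics can be produced from real data: feed `quantify` NIfTI
activity volumes (Bq/mL) plus a patients CSV and a label sidecar, or feed
`analyze` any per-lesion table with `patient_id, category, region,
suv_max` columns. The library API (`spectsuv.run_quantify`,
`spectsuv.run_analyze`, and the per-module functions) exposes every stage
programmatically.

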