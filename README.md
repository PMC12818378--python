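# myelimetric

Post-segmentation g-ratio morphometry for axon–myelin measurements.

Segmentation tools for electron-microscopy images produce tables of axon
diameters and myelin thicknesses, but the downstream analysis — cleaning,
g-ratio computation, caliber stratification, group comparison — is usually
done ad hoc in spreadsheets. `myelimetric` is a library and CLI that
standardizes that post-segmentation step for neurobiologists quantifying
myelin integrity (demyelination models, remyelination therapies,
neuropathies).

## The analysis

For an axon of diameter *a* wrapped by a sheath of one-sided radial
thickness *m*, the fiber diameter is *f = a + 2m* and the **g-ratio** is

&nbsp;&nbsp;&nbsp;&nbsp;*g = a / f = a / (a + 2m)*,

physiologically ≈ 0.6–0.8 in mammals; demyelination pushes *g* up. Under
the axomyelin-unit model *g* is approximately constant across calibers in
health, so the pipeline:

1. **cleans** the data (drop missing/invalid rows; exclude *a* < 0.15 µm and
   two-sided myelin < 0.03 µm as segmentation artefacts; remove fibers with
   *g* outside 0.5–0.9; every removal is logged with a reason code, and the
   threshold filters can be bypassed);
2. computes *f* and full-precision *g* (reported at 2 decimals);
3. derives **six diameter bins** from the control distribution and applies
   the same edges to every group;
4. reports per-bin mean/median/SD of *g* with Shapiro–Wilk normality and
   Hartigan dip multimodality diagnostics, a **constant-g grand mean** *ḡ*
   (least-squares constant fit to the six bin means), a fiber-vs-g
   correlation plausibility flag, and a **two-way group × bin ANOVA**
   (Type II SS) for treatment comparisons.

A fully parameterized synthetic generator produces control and
demyelinated-like conditions with mathematically exact ground-truth
g-ratios (five subgroups × 1000 axons, truncated-normal *g*, log-normal
axon calibers, 2 µm fiber cap, plus deliberately sub-threshold "extreme"
rows for sensitivity analysis); it doubles as the validation surface and
the test-fixture factory.

## Worked example

```python
from myelimetric import (SimConfig, GRatioModel, GRatioComparison,
                         simulate_condition, append_extremes)

cfg = SimConfig(seed=1)
ctl = append_extremes(simulate_condition(cfg, "CTL"), cfg)
exp = append_extremes(simulate_condition(cfg, "EXP"), cfg)
print(GRatioComparison(GRatioModel(ctl), GRatioModel(exp)).fit().summary())
```

prints (abridged):

```
G-ratio analysis: group CTL
records in: 5500   retained: 5000   excluded: 500
exclusions: axon_below_min=500
 bin       range (um)      n   mean g   median       sd
   1   0.504-0.753        40   0.7142   0.7117   0.0369
   ...
   6   1.751-2.000      1989   0.7065   0.7052   0.0298
grand mean g (constant-g fit to bin means): 0.7093   (n-weighted/pooled: 0.7071)

G-ratio analysis: group EXP
records in: 5500   retained: 4994   excluded: 506
grand mean g (constant-g fit to bin means): 0.8045   (n-weighted/pooled: 0.8031)

Two-way ANOVA (g ~ group * bin, Type II SS)
     group: df=    1 SS=   22.909944 F=23520.5721 p=0
       bin: df=    5 SS=    0.033827 F=    6.9458 p=1.748e-06
 group:bin: df=    5 SS=    0.005222 F=    1.0723 p=0.3735
  residual: df= 9982 SS=    9.722853
```

The 500 appended extreme rows per condition are exactly what cleaning
removes; the pooled means recover the imposed condition means (0.70
control, 0.80 demyelinated, the latter shifted slightly by truncation and
the fiber cap); the group effect is unambiguous while the group × bin
interaction is null, as imposed (the same g-shift in every caliber bin).

The same workflows are available from the shell:

```bash
myelimetric simulate --condition CTL --seed 1 --out ctl.xlsx
myelimetric simulate --condition EXP --seed 1 --out exp.xlsx
myelimetric analyze  --input ctl.xlsx --group CTL --out-dir out/
myelimetric compare  --control ctl.xlsx --experimental exp.xlsx --out-dir cmp/
```

Input workbooks pair columns by sample prefix (`<Sample>_Ax` in µm,
`<Sample>_My` two-sided µm; pass `--myelin one-sided` to double radial
measurements at load). Outputs are XLSX workbooks (cleaned data, bin
summaries, exclusion log), PNG plots and a `run_manifest.txt` with the
per-stage row-count chain.

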