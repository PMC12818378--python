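# Methods

## Measurement model and units

One record is one myelinated axon: axon diameter *a* (µm) and the
analysis-ready **two-sided** myelin thickness *My = 2m* (µm), where *m* is
the one-sided radial sheath thickness. Fiber diameter is *f = a + My* and
the g-ratio *g = a/f*, identical to the classical *a/(a + 2m)*. Workbooks
that store one-sided *m* must be doubled at load (`myelin="one-sided"`);
no auto-detection is attempted because the two conventions overlap
numerically.

All statistics use full-precision *g*. The conventional 2-decimal g column
(`g_ratio_2dp`, rounded half-away-from-zero) exists only for reporting:
rounding before averaging would bias a mean by up to 0.005, which is the
size of effect the pipeline is meant to resolve. Half-away-from-zero was
fixed because spreadsheet conventions expect 0.005 → 0.01; banker's
rounding would silently disagree with hand-checked outputs.

## Cleaning

Thresholds (defaults): axon diameter < 0.15 µm and two-sided myelin
< 0.03 µm are excluded as artefacts — axons below ~0.15 µm are rare and
inconsistently myelinated, and sheaths thinner than ~0.03 µm do not
insulate effectively. Comparisons are strict (`<`), so boundary values are
retained. A second filter removes fibers with *g* outside [0.5, 0.9], the
physiological plausibility window. Both filters are disabled together by
`enabled=False` (experimental tissue may legitimately contain extreme
values); removal of missing or non-finite/non-positive rows is never
bypassable because such rows are not measurements.

Every removed row is logged exactly once with its first matching reason in
the fixed order *missing → nonfinite_or_nonpositive → axon_below_min →
myelin_below_min* (then *g_out_of_range* at the later stage), which makes
the conservation identity `rows_in = rows_out + rows_logged` hold at every
stage; the run manifest records the chain.

The 0.03 µm myelin floor is applied to the stored (two-sided) column.
Whether the threshold was originally meant one- or two-sided is ambiguous;
for the generator's sensitivity rows the ambiguity is moot because their
axon diameters are below 0.15 µm by construction and the axon filter
removes them regardless.

## Binning

Six contiguous diameter intervals are derived from the **control** dataset
only and applied unchanged to all groups — the control is the
physiological reference frame, and shared edges are what make per-bin
comparisons meaningful. Six bins balance caliber resolution against
per-bin n. Defaults: the binned variable is fiber diameter (axon diameter
selectable, since both appear in practice) and edges are equal-width over
the control [min, max]; quantile edges are offered to equalize per-bin n
for small datasets. Intervals are [e_i, e_{i+1}) with the last closed
above. Experimental fibers outside the control range are clamped into the
first/last bin and counted rather than dropped, so cross-group
comparisons keep all cleaned fibers; the clamp count is reported.

## Statistics

Per bin: n, mean, median, sample SD (n−1) of *g*; Shapiro–Wilk (n ≥ 3,
skipped for constant data) and Hartigan's dip test (n ≥ 4). No
multiple-testing correction is applied across the six per-bin normality
tests; they are descriptive profiling, and raw p-values are reported.

**Grand mean.** The constant-g model fits a single *ḡ* to the six bin
means by least squares. Unweighted (the default) this is the arithmetic
mean of the nonempty bin means — each caliber cohort counts equally;
n-weighted it reduces exactly to the pooled mean over all fibers. Both are
reported.

**Group comparison.** Fixed-effects two-way ANOVA of *g* on group, bin and
their interaction via `statsmodels` OLS with Type II sums of squares —
per-bin n necessarily differs between groups, so a convention for
non-orthogonal designs is mandatory, and Type II is the standard choice
when the interaction is the question. Empty group × bin cells and zero
residual df are hard errors, not silent refits. Mixed-effects /
hierarchical models are out of scope; the cleaned per-fiber table exports
to R or statsmodels for that.

**Dip statistic.** Implemented in-package (no maintained dependency was
available): the greatest-convex-minorant / least-concave-majorant modal
interval iteration, jitted with numba. It is validated in the test suite
against an independent brute force that solves the defining problem
directly — the minimal band half-width d such that some unimodal CDF
(convex, then concave, with at most one atom at the mode) stays within d
of the ECDF, via linear-programming feasibility and bisection. P-values
are Monte-Carlo calibrated against the uniform null (the asymptotically
least favourable unimodal distribution) at the observed n, with a fixed
internal seed and `n_boot=200` by default, so results are deterministic;
null tables are cached per sample size.

**Plausibility flag.** Pearson correlation of fiber diameter with
full-precision g; flagged when |r| ≥ 0.3 and p < 0.05. Under the
axomyelin-unit model g is caliber-independent in health, so a strong
correlation suggests segmentation bias, resolution mismatch or sampling
artefacts. The 0.3/0.05 defaults are package choices (a medium effect at
conventional significance); the diagnostic never modifies data.

## Synthetic generator

Study conditions (defaults of `SimConfig`): two conditions, CTL with
ḡ = 0.70 and EXP (cuprizone-like) with ḡ = 0.80; five subgroups
("animals") per condition with zero-mean offsets δ ∈ {−0.02 … +0.02};
n = 1000 baseline axons per subgroup. Per axon: ln a ~ Normal(1.0, 0.5²);
g ~ Normal(ḡ + δ, 0.03²) truncated to [0.65, 0.95]; m solved from the
identity m = a(1/g − 1)/2, so pipeline-computed g equals the drawn g to
machine precision; (a, g) pairs failing the fiber cap f = a/g ≤ 2.0 µm are
redrawn jointly until the count is met (budget: 1000 × target draws, then
a hard error). Sensitivity rows: 100 per subgroup with
a ~ U(0.05, 0.149) µm and one-sided m ~ U(0.005, 0.029) µm — guaranteed
below both cleaning thresholds — with g recomputed from the identity and
the cap reapplied (vacuously, max f ≈ 0.21 µm). Totals: 5500 rows per
condition. Streams are seeded per (seed, condition, subgroup), so output
is independent of generation order.

Two axon-caliber presets ship because the two published descriptions are
irreconcilable: `printed` (the literal log-space µ = 1.0, σ = 0.5, whose
uncapped median is e¹ ≈ 2.72 µm, implying heavy rejection against the
2 µm cap) and `calibrated_iqr` (µ = ln 0.6 ≈ −0.51, σ ≈ 1.03, matching a
0.3–1.2 µm interquartile range). The literal parameters are the default
and define the validated study conditions; neither is asserted to be
"the" intent.

Two distortions of the nominal means are inherent to the design and show
up in validation numbers: truncation at 0.65 raises low-offset subgroup
means (by up to ≈ +0.009 at ḡ + δ = 0.68), and the joint fiber-cap
rejection tilts accepted g upward (≈ +0.004, since larger g admits larger
axons under the cap). Parameter-recovery checks therefore compare sample
means against the model-implied mean E[g·w(g)]/E[w(g)] with
w(g) = P(a ≤ 2g), computed by quadrature independently of the sampler.
The pooled CTL mean lands near 0.707 and the EXP mean near 0.803 (0.79
after rounding conventions in the reference outputs); both are within the
±0.015 validation band.

### What the generator does and does not emulate

It reproduces realistic caliber spectra, subgroup (animal-level)
structure, an exact axon–myelin–g consistency, and artefact-like outlier
rows. It does **not** simulate segmentation noise on a and m, oblique or
irregular sections, within-animal spatial correlation, or caliber-dependent
g (g is drawn independently of a). Passing validation therefore
demonstrates the correctness of the bookkeeping, the filters and the
statistics — not robustness to measurement error in real micrographs.

## Numerical and design notes

- Internal storage is full double precision; XLSX round-trips are exact to
  16 significant digits (the Excel numeric format written by openpyxl).
- Equal-width bin edges use `np.linspace`, making widths equal to 1e-9 or
  better; quantile edges that collapse under ties raise an error rather
  than silently merging bins.
- The dip p-value's uniform-null calibration makes the test conservative
  for peaked unimodal data; with the default n_boot = 200 the smallest
  attainable p is 1/201.
- The ANOVA type-I-error calibration test runs the two identical-generator
  conditions at 80 axons per subgroup with quantile bins over 1000
  replicates — a size chosen so every group × bin cell is reliably
  populated; calibration does not depend on n.
- Degenerate inputs fail loudly: degenerate control distributions, empty
  ANOVA cells, infeasible rejection sampling and non-positive measurements
  past cleaning all raise typed exceptions.

## Known limitations

- Only XLS/XLSX input is supported; CSV/Parquet dialects are future work.
- No statistical outlier detection beyond the fixed biological thresholds
  (no IQR/z-score/ML screening).
- Upstream segmentation errors cannot be detected or corrected here beyond
  the plausibility checks described above.
- Area-to-diameter conversion for irregular or obliquely sectioned axons
  is out of scope; inputs are assumed to be equivalent diameters.
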