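# Methods

## Scope and data model

`toxscreen` covers the computational layer of a quantitative LC–MSⁿ
emergency-toxicology screen: everything between integrated peak areas
and a clinical report.  Instrument control, chromatography, spectral
identification and wet-lab extraction are out of scope; inputs are
plain CSV tables of peak areas, and all concentrations are in ng/mL.

The reference panel bundled in `toxscreen/data/panel.csv` describes 69
analytes (62 drugs, 7 active metabolites).  Each entry carries five
ascending calibrator levels — calibrator 1 *is* the LLOQ and
calibrator 5 the ULOQ, by design of the screen — QC low/high levels,
the weighting label of the calibration model, and literature
therapeutic/toxic reference ranges.  Two rows (nordiazepam,
paliperidone) are dual-status compounds that can be parent drugs or
metabolites; both count as metabolites and carry a `dual_status` flag.
Four drug/metabolite pairs (diazepam, doxepin, risperidone,
venlafaxine) have *summed* reference ranges, marked by `sum_group` +
`range_is_sum`; banding over the sum is opt-in and requires the
partner concentration explicitly — missing partners are never imputed.
Two transcription notes: biperiden's QC high is stored as 400 ng/mL
(the printed 1600 exceeds its 500 ng/mL ULOQ and contradicts every
comparable entry), and tilidine's unusual QC low of 300 ng/mL is kept
verbatim.  Working-solution assignments and retention times are not
part of the bundled panel; selectivity checks therefore take a
per-call retention-time map.

## Calibration

The response model is linear in concentration on the IS-ratio scale,
y = a·x + b, fitted by weighted least squares with weights
w ∈ {1, 1/x, 1/x², 1/y, 1/y²}.  The intercept is always estimated,
matching the stored-calibration schema that carries one; forcing
b = 0 is not supported.  Fit quality is summarized by the
scale-free Σ((x̂ᵢ−xᵢ)/xᵢ)² (squared relative back-calculation errors),
which is comparable across weightings and concentration ranges.

**Weighting selection** runs on ≥2 (typically 3) replicate curves in
two stages.  Stage 1 decides *whether* the noise is heteroscedastic: the
response ratios observed at each level are pooled across replicates and
the within-level deviations are scored under two Gaussian variance
models, Var = σ² and Var = σ²x², by maximum likelihood (score
df·ln(Σw·d²/df) − Σdf·ln w; lower wins).  Homoscedastic scatter keeps
equal weighting.  Stage 2, reached only for heteroscedastic scatter,
picks among 1/x, 1/x², 1/y, 1/y² by the smallest relative-SSR total.
This two-stage design is deliberate: selecting purely by relative SSR
can never return equal weighting, because relative errors are dominated
by the lowest calibrators and a 1/x²-style fit always reduces them,
whatever the true noise law.  Measured at the study design (5 levels ×
3 replicates, 200 seeds): equal is chosen 94% of the time under
constant noise and a 1/x-family label 96% of the time under
proportional noise (sd = 0.05·conc).  The pure relative-SSR rule
remains available via `criterion="relative_ssr"`.  Selection pools the
decision across replicates rather than selecting per replicate; ties
break toward the simpler model (equal > 1/x > 1/x² > 1/y > 1/y²), with
tie detection at ~1e-9 relative resolution so that noiseless data —
where every weighting is exact — resolves to equal.  A separate
variance-ratio diagnostic (`heteroscedasticity_ftest`, highest vs
lowest calibrator across replicates) is reported but does not drive
selection.

**Mandel's linearity test** compares unweighted linear and quadratic
fits: F = (SSE₁ − SSE₂)/(SSE₂/(n−3)) against F(1, n−3), linear accepted
when p ≥ α = 0.05.  Weighted residuals are not used; the classical
procedure is unweighted.  With five calibrators the denominator has
2 df, so the test has little power to detect curvature — the function
warns for n ≤ 5.  Numerically, SSE₂ is clamped to ≤ SSE₁ (the models
are nested; round-off can violate this by ~1e-16) and SSE₂ = 0 maps to
F = ∞, p = 0.

**Back-calculation acceptance** follows the EMA rule: per-level bias
100·(x̂−x)/x within ±15%, ±20% at the LLOQ level, and the curve passes
when at least ⌈0.75·n⌉ levels pass — 4 of 5 for this design.

## Quantification and interpretation

Routine samples convert as x = (y − b)/a using the record's *working
slope*: the arithmetic mean of the stored 5-point slope and all
accumulated 1-point slopes (the stored slope is never replaced, only
averaged).  Censoring is exhaustive and exclusive: `nd` when no analyte
peak was integrated (area absent or zero), `below_lloq`/`above_uloq`
outside the calibrated range (no numeric value is reported there — in
this screen exceeding the ULOQ already implies severe intoxication and
dilution re-assay is deliberately unsupported), `value` otherwise.  A
detectable peak below the LLOQ is `below_lloq`, never `nd`; the two
mean different things in proficiency testing.

Interpretation bands a value against the literature ranges with
inclusive bounds; `toxic_above` is read as ≥.  Where the printed ranges
overlap (carbamazepine's toxic threshold of 10,000 ng/mL sits inside
its 2000–12,000 therapeutic range; also moclobemide, sertraline,
tramadol), the toxic verdict wins — the safety-conservative reading.
Entries with no ranges at all (the nor-metabolites) are
`not_interpretable`.  Analytes with a therapeutic range but no printed
toxic threshold (tapentadol, tilidine) cap at `above_therapeutic`.

**1-point recalibration** analyzes a fresh calibrator at the stored
1-point concentration (calibrator 3) in triplicate; the observed slope
(mean ratio − b)/x is appended to the record's history.  The intercept
is kept fixed — the stored-calibration schema tracks slope history
only, and refreshing b from a single level would confound slope and
intercept drift; an option point for future work.  Consistent ratios
are a fixed point of the record.

**QC-drift monitoring** evaluates a time-ordered QC-high series against
the ±30% limit (inclusive: exactly 30% passes).  Two *consecutive*
failures trigger a 1-point recalibration, attributed to both points; a
failure at the very next point after that adjustment escalates to a
fresh 5-point calibration.  Any passing point, and any fired action,
resets the episode.  When a 5-point calibration replaces the store, the
old CSV is archived (`<stem>.archive-<n>.csv`) and a new one starts
with empty history.

## Validation statistics

All acceptance bounds are inclusive and every decision is a pure
function of inputs and an `AcceptanceThresholds` record (±15/20%
back-calculation, ±30% accuracy/precision/matrix/QC, ±25% ionization,
20%/5% carry-over, ±0.4 min retention window, α = 0.05).

- **Matrix effects** (GTFCh): matrix factor % = 100·mean(post-extraction
  spiked donor areas)/mean(neat areas) at QC low and high, six donors;
  the CV is that of the per-donor factors.  Reported analyte-only, as
  the underlying protocol compares raw areas; an IS-normalized variant
  can be built from the same primitives.
- **Accuracy/precision**: within-run from one run of ≥5 replicates
  (bias of the mean, CV = sd/mean); between-run from ≥3 days × ≥5
  replicates.  The between-run CV defaults to the intermediate-precision
  CV from one-way ANOVA variance components with runs as groups
  (s²ᵢₚ = s²within + max(0, (MSB−MSW)/n₀), negative between-run
  components truncated at zero, n₀ the unbalanced-design effective group
  size); a plain pooled CV is available via
  `between_run_method="pooled"`.  Note the acceptance region is not a
  power guarantee: batches generated with true bias and CV of 20% — well
  inside the ±30% limits — still fail in roughly 6–20% of simulations at
  n = 3×5, purely from sampling scatter of the grand mean.  The
  suite's power property is therefore checked at 15%/15%, where the
  ≥95% pass rate genuinely holds.
- **Ionization effects**: IS-normalized mixture vs single-solution
  areas (triplicates), deviation within ±25%.
- **Carry-over**: blank injected after calibrator 5; analyte response
  must stay *below* 20% of an LLOQ sample's response, IS below 5%
  (strict <, "less than").
- **Selectivity**: blank-donor signals are flagged when they fall
  within ±0.4 min of an analyte's retention time *and* reach the
  carry-over threshold (20% of the LLOQ response).

The module also records the panel's validation outcome: ten analytes
exceeded the ±30% accuracy/precision limits (aripiprazole,
diphenhydramine, ketamine, melperone, pethidine, sertraline, tilidine
and nortilidine within-run; olanzapine and norpethidine additionally
between-run), leaving 59 fully validated.

## Proficiency-test adjudication

PT rows carry a calculated value that may be censored: `<X` (detected
but below the LLOQ X) or `nd` (not detected).  Verdicts: a numeric
value passes iff it lies in the accepted range (inclusive); a `<LLOQ`
result is *consistent* with the acceptance range whenever that range
reaches below the LLOQ (`accepted_low < lloq`) and then passes as
`Passed_below_LLOQ`, otherwise it fails because a quantifiable result
was expected; `nd` always fails (detection is always expected),
annotated `Failed_below_LLOQ` when even the target was below the LLOQ.
The LLOQ is resolved per row: an explicit override, then the LLOQ
recorded with the PT row (reports state the LLOQ in force at
measurement time, which can differ from the current panel — melperone's
PT rows carry 1000 ng/mL against the panel's 100), then the `<X`
censoring limit, then the panel.

Replaying the bundled 115-row PT table against its printed comments
reproduces 113 of 115 (98.3%).  The two discordant rows are the known
internally inconsistent zuclopenthixol entries (a `<50` with target
8.49 printed *Failed* although the identical haloperidol pattern
passes, and an `nd` printed *Passed (< LLOQ)*); they are detected, not
special-cased.  Concordance compares the pass/fail outcome; a
difference only in the "(< LLOQ)" annotation (one zopiclone row) is
listed separately, since the printed comments annotate that case
inconsistently themselves.

## Synthetic data

The generator emulates exactly the structure the method assumes:
ratio = a·x + b + ε with sd(ε) = c + p·x (constant plus proportional,
so proportional-dominant settings reproduce the heteroscedasticity that
justifies the panel's predominant 1/x² weighting), lognormal IS areas
(mean 10⁶ counts, CV 5% by default) sampled independently per
injection with analyte area = ratio × IS area, per-donor multipliers on
post-extraction-spiked responses for matrix-effect studies, and a
multiplicative slope decay per day for drift studies (true slope
(1−δ)ᵗ·a, so the expected QC deviation at day t is (1−δ)ᵗ−1 for b = 0).
The default monitoring design is 48 points at a 14-day cadence — two
years of biweekly QC.  All randomness flows through
`numpy.random.default_rng` (PCG64); a fixed seed reproduces
byte-identical tables, and every generated set can be archived with its
JSON config.  Deliberately *not* emulated: chromatographic peak shapes,
spectra, retention-time drift, carry-over memory between simulated
injections, and non-Gaussian outliers — so passing tests demonstrate
correctness of the statistics, not robustness to pathological real-world
signals.

## Problem sizes and determinism

Simulation-based checks use sizes at which their statistics are stable:
100–200 seeded replicates for oracle-equivalence, slope-recovery and
weighting-selection rates, and a single 48-point series for QC-drift
replay; the whole suite and the acceptance script each run in well
under a minute.  `scripts/acceptance.py` derives every stream from its
`--seed` via `numpy.random.SeedSequence`, keeping derived seeds below
2³¹.

## Known limitations

- Quantification above the ULOQ is censored, never extrapolated or
  dilution-corrected, by design of the screen.
- The stored calibration carries no uncertainty; QC monitoring, not a
  confidence interval, is the guard against drift.
- The weighting-selection variance gate needs replicate structure; with
  unreplicated curves it falls back to the relative-SSR rule, which is
  biased toward 1/x-family labels.
- Mandel's test at n = 5 has very low power; a passing test is weak
  evidence of linearity on its own.
- Interpretation bands come from literature ranges transcribed with the
  panel; they are reference points, not clinical advice.
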