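# toxscreen

Automated quantification engine for LC–MSⁿ drug screening in 24/7
emergency toxicology.

Emergency-toxicology laboratories must report, within minutes of a
screening hit, whether a patient's plasma level of a drug is
therapeutic, supratherapeutic or toxic.  `toxscreen` implements the data
side of such a screen for a 69-analyte panel (62 drugs plus 7 active
metabolites — benzodiazepines, antidepressants, neuroleptics,
analgesics, anticonvulsants and others): weighted linear calibration
with data-driven weighting selection and Mandel linearity testing, an
*electronically stored* 5-point calibration that is reused across runs,
kept honest by biweekly QC monitoring and refreshed by fast 1-point
recalibrations, censored quantification with therapeutic/toxic
interpretation, GTFCh/EMA validation statistics, and adjudication of
interlaboratory proficiency tests.

## The model

Quantification uses the internal-standard-normalized response of each
analyte (peak area over the trimipramine-d₃ IS area), assumed linear in
the plasma concentration *x* (ng/mL):

    y = a·x + b + ε,   ε ~ N(0, σ(x)²)

Calibration fits *a*, *b* by weighted least squares with weights
w ∈ {1, 1/x, 1/x², 1/y, 1/y²} to absorb heteroscedastic noise.  The
weighting is chosen from three replicate curves: a Gaussian
maximum-likelihood comparison on the within-level replicate scatter
decides whether the variance grows with concentration, and the winning
family is refined by the smallest summed squared relative
back-calculation error Σ((x̂ᵢ−xᵢ)/xᵢ)².  Linearity is checked with
Mandel's fitting test, F = (SSE₁ − SSE₂)/(SSE₂/(n−3)) against F(1, n−3)
at α = 0.05, and each calibrator must back-calculate within ±15% (±20%
at the LLOQ), with at least 75% of levels passing (4 of 5 here).

Routine samples are quantified as x = (y − b)/a against the stored
calibration, censored outside [LLOQ, ULOQ] (calibrators 1 and 5), and
banded against literature therapeutic/toxic ranges.  A QC-high sample
every two weeks monitors drift: two consecutive deviations beyond ±30%
trigger a 1-point recalibration (the new slope is averaged into the
stored record), and a failure persisting right after that triggers a
fresh 5-point calibration.

## Worked example

Fit a calibration from three synthetic replicate curves of the
alprazolam design and quantify a case sample:

```sh
toxscreen simulate --out calibrators.csv --seed 11 \
    --levels 50,125,250,375,500 --replicates 3
toxscreen calibrate --panel panel.csv --measurements calibrators.csv \
    --out store.csv
toxscreen quantify --panel panel.csv --store store.csv \
    --measurements case.csv --out results.csv --report report.txt
```

`calibrate` prints the fit diagnostics per analyte:

```
Alprazolam: weighting=1/x2 slope=0.00199247 intercept=0.00119461 mandel_linear=True backcalc=15/15 pass=True
```

— the selected weighting, the fitted slope/intercept (truth here was
slope 0.002, intercept 0), Mandel's verdict that a straight line
suffices, and 15 of 15 calibrator points back-calculating within the
EMA limits.  The case report then reads:

```
case-001  Alprazolam: 260.4 ng/mL (toxic) [therapeutic 5-50, toxic above 100 ng/mL]
```

i.e. the measured response converts to 260.4 ng/mL, inside the
calibrated range 50–500 ng/mL, and far above alprazolam's 100 ng/mL
toxicity threshold — the band a clinician acts on.

The same operations are available as a library
(`toxscreen.fit_weighted_linear`, `toxscreen.quantify`,
`toxscreen.qc_monitor`, ...); `toxscreen.load_reference_panel()` returns
the bundled 69-analyte panel and `toxscreen.load_reference_pt_table()`
the bundled proficiency-test results.

## Layout

- `src/toxscreen/panel_io.py` — data model and CSV I/O (panel,
  calibration store, measurements, PT tables)
- `src/toxscreen/calibration.py` — WLS fitting, Mandel test, weighting
  selection, back-calculation acceptance
- `src/toxscreen/quantify.py` — stored-calibration quantification,
  interpretation, 1-point recalibration, QC monitoring
- `src/toxscreen/validation.py` — matrix effects, accuracy/precision,
  ionization effects, carry-over, selectivity
- `src/toxscreen/proficiency.py` — PT adjudication
- `src/toxscreen/synthetic.py` — seeded synthetic measurement generator
- `src/toxscreen/cli.py` — the `toxscreen` command
- `docs/methods.md` — models, assumptions, numerical choices and
  limitations
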