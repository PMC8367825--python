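# Methods

This note documents the models, conventions and default parameters the
package implements, in enough detail to reproduce any number it prints.

## Optical model

Diffuse reflectance in each narrow band is modelled with a modified
Beer–Lambert law over two chromophores, oxy- and deoxyhaemoglobin:

```
R(λ) = k(λ) · exp( −d · ( ε_HbO2(λ)·C_HbO2 + ε_Hb(λ)·C_Hb ) )
```

* `k(λ)` — bloodless-tissue baseline reflectance, dimensionless in (0, 1].
* `d` — mean optical path length through the sampled mucosa, cm.
* `ε` — molar extinction, cm⁻¹·mM⁻¹; `C` — concentration, mM.

The exponent carries an explicit negative sign: absorption must reduce
reflectance, so the ratio R610/R545 *increases* with total haemoglobin
(545 nm is absorbed far more strongly than 610 nm).  Writing the exponent
without the sign would invert that monotonicity and contradict the
clinical ordering of the three classes, so the signed form is used
throughout, and `ln(R/k)` is negated during inversion.

Default optical constants (rounded representative values for whole blood
in the visible range):

| band | ε_HbO2 | ε_Hb | k |
|------|--------|------|------|
| R545 | 52 | 48 | 0.80 |
| R575 | 59 | 37 | 0.82 |
| R610 | 1.10 | 8.25 | 0.90 |

The 545-to-610 extinction contrast is 52/1.10 ≈ 47 for HbO2 and the
oxygenation-weighted contrast stays in the 7–8× band quoted for green
versus red absorption of mixed blood.  Path length defaults to
`d = 0.25 cm`.  Oxygen saturation by lesion grade defaults to 0.98
(normal), 0.85 (OPML), 0.70 (SCC), reflecting progressive hypoxia.

### Chromophore inversion

Two reflectance bands give two linear equations in (C_HbO2, C_Hb);
the 2×2 extinction matrix is inverted analytically.  Pixels whose
denominator band falls below 1/255 of full scale, or that are saturated in
any band, are marked invalid.  Negative recovered concentrations are
clipped to zero and flagged.  StO2 = C_HbO2 / tHb is reported only where
tHb exceeds 1e-6 mM; elsewhere it is NaN.

### Target-ratio inversion

The phantom places lesions by the ratio they should exhibit at the core.
Given a target ratio `r`, saturation `s` and optics, total haemoglobin is

```
tHb = ln( r · k545 / k610 ) / ( d · (g545 − g610) )
```

with `g(λ) = ε_HbO2(λ)·s + ε_Hb(λ)·(1−s)`, then
`C_HbO2 = s·tHb`, `C_Hb = (1−s)·tHb`.  Substituting back reproduces the
requested ratio exactly (round-trip error ~1e-15 in tests).

## Digital phantom

Scenes are rasters (default 128×128) with a uniform background
(C_HbO2 = 0.012 mM, C_Hb = 0.003 mM, ratio ≈ 1.35), elliptical lesions
with a 2-pixel cosine edge taper, optional inflammation patches (scaled
C_Hb), specular spots (pixels forced to full scale and flagged
saturated), and a fluorescence channel that loses intensity inside
lesions with a small protoporphyrin-IX gain term.  Gaussian noise is
seeded and clipped to [0, 1].  The phantom emulates the *image statistics*
the analysis consumes — band intensities, ratio contrast, saturation,
taper — not radiative transport: there is no scattering model, no depth
structure, and fluorescence is phenomenological.

## Score cohorts

Class score distributions are log-normal, calibrated in closed form from
a median `m` and inter-quartile range `q`:

```
μ = ln m          σ = asinh( q / (2m) ) / z₀.₇₅
```

where z₀.₇₅ is the standard-normal upper quartile.  This follows from the
quantile function of the log-normal: the quartiles are
`m·exp(±σ·z₀.₇₅)`, so `q = 2m·sinh(σ·z₀.₇₅)`.  Defaults are
median/IQR = 1.41/0.55 (normal), 3.04/0.98 (OPML), 3.59/1.07 (SCC);
tests confirm 5000-sample cohorts reproduce these within 5% (medians)
and 10% (IQRs).

## Exposure calibration

Each retry captures all four bands, computes frame means, and declares
convergence when every mean is within a tolerance of the grand mean *and*
no frame is fully pinned at full scale (a saturated frame satisfies any
mean test trivially but carries no information, so it can never
converge).  The tolerance loosens linearly from 2.5% at retry 0 to 4% at
the final retry (default `max_retries = 5`).  On convergence the returned
exposures are rescaled globally toward a mid-scale level of 0.5; on
failure each band is rescaled by `grand_mean / band_mean` (clipped to
[0.1, 10]) and the loop retries.  Linear cameras with gain spreads up to
8× converge within two retries.

## Lesion scoring

* **Hotspot** — the brightest *valid* ratio pixel inside the lesion ROI.
  Ties break row-major (smallest y, then smallest x), matching flat
  argmax order, so results are deterministic.
* **Score** — mean ratio over the 5×5 window centred on the hotspot.
  The window is clipped at image borders; invalid pixels are excluded
  from the mean; window pixels need *not* lie inside the ROI, since the
  window characterises the local neighbourhood of the hottest point
  rather than the ROI outline.
* **Healthy reference** — mean over the valid pixels of a healthy ROI;
  `suggest_healthy_roi` scans all fully-valid windows disjoint from the
  lesion ROI and returns the lowest-mean one (row-major tie-break).
* **ROI rasterisation** — even–odd crossing test against pixel centres at
  integer coordinates, with half-open edge handling so shared edges are
  counted once.

## Triage thresholds

`t_opml = (mean(normal) + mean(OPML)) / 2` and
`t_scc = (mean(OPML) + mean(SCC)) / 2` — the mean-of-means rule.  A score
exactly on a boundary is assigned to the *higher-risk* class, since the
clinical cost of a missed referral exceeds that of a false alarm.  The
suspect/critical boundary extends the same rule to the SCC class,
anchored by the observation that scores above ≈3.6 are dominated by
malignant sites.  Models are versioned in an append-only registry
(`records.jsonl` plus immutable `models/<group>/vN.json` snapshots) so any
historical model can be replayed from the log prefix that produced it.

Site groups: thresholds may be fitted per anatomical group — keratinized
(gingiva, vermillion border, dorsal tongue, hard palate, alveolus) versus
non-keratinized mucosa — or per site, because baseline vascularity and
keratin masking shift the normal ratio distribution between groups.

## Diagnostic metrics

* Sensitivity/specificity are percentages; PPV/NPV fractions.  Undefined
  rates (zero denominators) are `None`, never exceptions.
* A score equal to the cutoff is called positive (consistent with the
  higher-risk boundary rule).
* ROC-AUC uses the Mann–Whitney U statistic with midranks, so ties
  contribute ½ — identical to the exhaustive pairwise win fraction.
* Class summaries use linear-interpolation quantiles (the `p·(n−1)` rule)
  and report outliers above the Tukey upper fence `q3 + 1.5·IQR`
  (strictly above).

## Problem sizes used in validation

128×128 phantoms for inversion recovery (error < 1e-6 mM required,
~1e-16 observed); 50 random target-ratio round trips at 1e-9; 100+
random instances per brute-force oracle comparison (ratio maps, hotspot
scoring, healthy-ROI search, ROC-AUC); 5000-per-class cohorts for
distribution calibration; a 200-site cohort with a 50/50 split for
held-out triage accuracy.

## Limitations

The phantom is statistical, not physical: it cannot probe scattering,
depth-dependent sampling, or cross-talk between fluorescence and
reflectance channels.  The two-chromophore inversion ignores melanin and
other absorbers, so absolute concentrations on real tissue carry model
bias even when ratios rank lesions correctly.  Threshold models assume
score distributions are stationary between training and deployment
cohorts; the registry records provenance precisely so that drift can be
audited.
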