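# Methods

## The screen model

The generative model mirrors an arrayed CRISPR knockout rescue screen against
a degrader compound read out by dual luminescence. Each library well holds one
gene's pool of 3–4 sgRNAs; library source plates are stamped into triplicate
384-well assay plates, so one gene occupies one well per replicate (three
wells total, M = 2829 ranked wells when all 943 genes pass QC). Sixteen wells
per plate are controls: media-only and non-infected/puromycin-killed wells
(the Firefly QC reference), positive-control wells carrying guides against
the hijacked E3 ligase receptor (full rescue), and non-targeting guides.
Control positions are scattered at random by default (an edge layout is
available); the true layout of the emulated screen is not published.

Per well, cell number N is log-normal around a plate mean (plate effect
sigma 0.1, well sigma 0.2), Firefly = gain · N · (1 + ε) with measurement CV
5%, and the untreated ("baseline") HiBiT is a strictly increasing cubic of
the observed Firefly, times an independent 5% noise term. The degrader
removes a fraction d = 0.9 of HiBiT in non-rescued wells. Knocking out a
rescuer restores a fraction ρ of the *degraded span*:

    treated / baseline = 1 − d + ρ·d

so ρ = 1 is exactly full restoration and ρ = 0.5 gives 0.55 of baseline at
d = 0.9. Guide-potency heterogeneity enters as per-well Beta jitter of ρ
around the gene value (concentration κ = 50). Infection failures are drawn
per library *source* well at rate 117/943 ≈ 0.124 — a bad virus well fails in
all three stamped replicates, which is why failures aggregate at the gene
level — and leave Firefly at the background level of the killed controls.
Ground truth records every well's noiseless rescue ratio relative to the
non-hit baseline, (1 − d + ρd)/(1 − d), the planted gene set, and the failed
wells.

What the generator does *not* emulate: spatial (row/column/edge) plate
gradients beyond the Firefly-coupled cell-number variation, guide-level
off-target effects, cell-cycle or growth dynamics, and luminescence
saturation. Passing tests therefore certify the statistical pipeline under
Firefly-explainable nuisance structure, not robustness to spatial artifacts
a real screen may add.

## QC, normalization, robust z

The QC gate is a ratio test: a well passes when log10(Firefly / reference)
exceeds log10(1.25), with the reference the per-plate median Firefly of the
media/non-infected controls. Reading the threshold as a ratio to controls
makes it scale-free (plate gain cancels); applying it to raw log10 Firefly
would tie the threshold to instrument units.

Each assay plate's HiBiT ~ Firefly relation is fit with a third-order
polynomial over the QC-passing library wells (mapped-domain least squares for
conditioning, coefficients reported in the power basis). Because rescuers are
rare, the all-well fit approximates the *treated non-hit* baseline; one
robust re-fit pass drops points with absolute residual above 3 scaled-MADs so
strong rescuers do not bend it. Consequently a non-hit well's relative change
(observed / predicted HiBiT) is 1, and a full-rescue well's is
1/(1 − d) = 10 at d = 0.9. On noise-free cubic data the normalization is
exact: rel_change is constant across non-hit wells to machine precision. The
robust baseline assumes contamination well under the 3-MAD breakdown —
around 10% rescuers is safe, ~40% is not (tested).

Activity is the robust z of rel_change, z = (x − median)/(1.4826·MAD),
computed per assay plate by default (matching the plate-level normalization
granularity; a screen-wide option exists), with an SD fallback at MAD = 0 and
all-zeros when the SD also vanishes. Prediction outside a plate's fitted
Firefly domain clamps to the domain edge and flags the well; a non-positive
prediction QC-fails the well with a reason rather than raising.

## RSA scoring and hit calling

The gene score is the minimum hypergeometric upper tail over the gene's rank
prefixes (see README), computed with log-gamma binomials and log-sum-exp;
exactness is certified against exhaustive rational-arithmetic enumeration
(all configurations with M ≤ 12, N ≤ 4 agree within 1e-9 in log10 space) and
cross-checked against an independent library implementation at M = 2829.
Ties take the largest rank of their block, so a constant activity vector
yields P = 1 for every gene. Genes with fewer than 2 QC-passing wells are
reported as QC-excluded with no score (never P = 1); their wells still enter
the ranking population M.

The permutation null shuffles robust-z values among QC-passing library wells
within each assay plate (100 permutations by default) and re-scores all genes
identically to the observed run. The plug-in FDR divides the mean null
exceedance at the threshold by the observed exceedance; hits below −4 are
"strong", between −4 and −3 "weaker". Two properties of this construction
are worth knowing:

- On null screens it is well calibrated: observed and permuted exceedance
  agree within Monte-Carlo error, and the gene-level tail respects the
  N·α union bound.
- With strong planted hits it is *conservative*: the permuted null
  redistributes the rescuers' extreme activities across genes (occasionally
  stacking two in one gene), while in the observed ranking the hits occupy
  the top ranks and push every null gene down, suppressing realized false
  positives. The report therefore upper-bounds the realized
  false-discovery proportion (measured ~6–7% reported vs ~1–2% realized at
  the default conditions); the tests assert the estimate is never
  anti-conservative beyond 2×.

Pipeline sensitivity is defined over *scoreable* planted hits: a planted
rescuer whose virus well failed infection is reported in the QC-excluded
category, which is its correct disposition, and cannot count as a miss.

## Dose-response and the viability window

4PL fits use unweighted least squares on
y = bottom + (top − bottom)/(1 + (x/ec50)^hill), initialized from the data
quartiles, with the orientation canonicalized (bottom ≤ top; the swapped
parameterization with negated Hill slope is the identical curve). For
DMSO-normalized descending degradation data, rel DC50 is the fitted midpoint,
Dmax = 1 − bottom (fitted plateau, not best observed dose), and the absolute
DC50 solves the fitted curve at 0.5 analytically,
abs_dc50 = ec50·((top − 0.5)/(0.5 − bottom))^(1/hill), absent when 0.5 lies
outside (bottom, top).

The flow workflow reduces technical replicates medians-first, subtracts
background from GFP and mCherry before the ratio, excludes doses whose
DMSO-relative viable-gate fraction falls below the 25% floor from the
degradation fit, and takes GI50 as the midpoint of the descending viability
fit (absent when the curve never reaches half-killing). The viability window
V/D = GI50/DC50 substitutes the top assessed dose for a missing numerator or
denominator; with both missing it degenerates to 1.0 with both flags set.
V/D is scale-invariant in concentration units.

Recovery study sizing: with 8 doses in triplicate at 5% multiplicative CV and
unweighted least squares, the ec50 sampling error is ~9% (1 sigma) for a
Hill-1 curve — no dose placement brings 95% of fits within 10% — and ~4% for
a Hill-2 curve. The recovery benchmark therefore simulates a steep curve
(Hill 2), representative of catalytic degrader dose-responses; Hill-1
behavior is covered by exact-data round-trips at machine precision.

## Ternary binding and kinetics

The hook-effect isotherm is modeled as the product of an ascending and a
descending hyperbola, R(c) = rmax·[c/(kd₁+c)]·[kd₂/(kd₂+c)] — on a log axis
exactly two separated sigmoidal transitions with unit Hill slopes, apparent
K_Ds at the two midpoints, and an analytic peak at √(kd₁·kd₂). The model is
deliberately phenomenological: a full mass-action ternary equilibrium with
explicit cooperativity and species conservation is out of scope. K_Ds are fit
in log space; the parameterization's swap symmetry (kd₁↔kd₂ with rmax
rescaled by kd₂/kd₁ is the same curve) is resolved by canonical ordering.
Monotone data are rejected with a pointer to a binary model.

Dissociation traces are fit per-trace as baseline + amplitude·exp(−k_off·t);
residence time defaults to the off-rate inversion 1/k_off, with a
ln(2)/k_off half-life option. Cooperativity is the fold-shift
IC50(binary)/IC50(ternary with saturating partner); values above 1 indicate
positive cooperativity. Initial velocities are ordinary least-squares slopes
over the earliest 20% of a kinetic trace, halving the window while the
quadratic curvature term is significant at p < 0.05 (minimum 5 points), which
keeps the estimate within ~5% of the analytic t = 0 rate on saturating
exponentials.

## Numerical and interface choices

- Hypergeometric tails: in-house log-space computation (direct factorials
  overflow at M ≈ 2829); permutation scoring is vectorized over all gene
  prefixes at once.
- Polynomial fits: `numpy.polynomial.Polynomial.fit` in a mapped domain,
  converted to power-basis coefficients for reporting.
- Curve fits: `scipy.optimize.curve_fit` with data-driven initialization;
  non-convergence raises a fit error with diagnostics rather than returning
  silently bad parameters.
- CSV dialect: comma-separated UTF-8 with mandatory headers; guide pools
  serialized semicolon-joined; well IDs case-insensitive on read and
  canonicalized (upper-case, zero-padded) on write; floats written with
  `repr` so tables round-trip losslessly. `#` lines are provenance comments
  (the pipeline stamps a config hash and seed).
- Determinism: a single seed fans out through independent substreams
  (library, layout, infection failures, per-plate noise), so identical
  configs are byte-identical and a single plate can be regenerated.

## Problem sizes used in the shipped studies

The analysis drivers and acceptance script run the full-size screen
(943 genes × 3 replicates, ~2973 wells) with 100 permutations; the
calibration study uses 20 null + 20 planted screens at 20–50 permutations
each; recovery studies use 200 seeded 4PL fits and 100 seeded bell fits.
These sizes give Monte-Carlo errors comfortably below the asserted margins
while keeping the whole suite fast on one CPU.

## Known limitations

- The RSA variant is the core min-hypergeometric statistic without internal
  multiple-testing correction; calibration is purely empirical via the
  permutation null, so reported P values are not familywise-adjusted.
- "Max rel. change" summarizes a gene by its best well; a single outlier
  well in a QC-passing gene can inflate it (the P value, which needs
  consistent ranks, is the guard).
- The plug-in FDR is conservative in strong-signal regimes (see above).
- Guide-level deconvolution within pooled wells is not identifiable in this
  arrayed design and is not attempted.
- The bell model's unit Hill slopes can bias apparent K_Ds when the true
  transitions are cooperative; the fit quality (RSS) should be inspected
  before interpreting K_Ds from unusual isotherms.
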