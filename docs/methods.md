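# Methods

This note records the models, defaults and numerical choices behind
`imotifkit`, and what the synthetic generators do and do not emulate.

## Repeat scanning

Elements are maximal tandem runs of whole 4-mer units (default TCCC) on
either strand; partial trailing units are never counted, because repeat
copy number n is defined in whole units. Runs of the reverse complement
(GGGA) are the same repeat seen from the G-rich strand and are reported as
C-rich elements on the minus strand; all coordinates are 0-based half-open
BED convention on the forward strand of the input. An N terminates a run
(no ambiguity-tolerant matching). Because TCCC is not self-overlapping,
maximal runs are unique and phase ties cannot occur. Folding-competence
flags are thresholds on n — G4-competent for n > 3, i-motif-competent at
neutral pH for n ≥ 7, transitional pH above 7 for n ≥ 9 — and are
upward-closed in n. Oligo-dC runs are annotated against the empirical
(4n−1) rule: a run of m cytosines folds optimally near neutral pH when
m ≥ 11 and m ≡ 3 (mod 4) (lengths 11, 15, 19, 23).

## Melting analysis

**Estimator.** The melting (Tm) and annealing (Ta) temperatures are the
temperatures of the global extremum of |dA/dT| ("first-derivative
method"). The signal is first smoothed by a moving-window local quadratic
least-squares fit (default window 5 points) — unsmoothed central
differences are noise dominated — then differentiated by central
differences on the (possibly uneven) grid, and the extremum refined below
grid resolution by a parabola through it and its two neighbours. The
absolute derivative is used because i-motif melting at 295 nm is
hypochromic (negative slope) while other bands melt with positive slope.
Duplicate-temperature points (instrument hold segments) are dropped before
analysis. A curve is declared transition-free — an explicit `None`, never
a number — when the smoothed signal's amplitude does not exceed 8× the
robust (MAD-based) residual noise left by smoothing; an amplitude-based
guard is used because a broad transition (|ΔH| ~ 20 kcal/mol) spreads
|dA/dT| over most of the grid and any derivative-distribution test would
reject it.

**Replicates.** Midpoints are estimated per replicate and then averaged
(sample SD, ddof 1), matching instruments analysed ramp by ramp.
Hysteresis defaults to tm_mean − ta_mean; a per-replicate-pair mode is
also exposed, because published tables are consistent with one convention
for most rows and the other for at least one. The bundled pH 6.5 table is
checked row by row: at a 0.15 °C tolerance (printed precision is 0.1 °C),
8 of 9 rows are internally consistent; the n = 15 row differs by 1.0 °C
and is flagged rather than silently corrected, since the printed values
are kept verbatim.

**TDS.** The thermal difference spectrum is the 95 °C spectrum minus the
4 °C spectrum on the folded grid (linear interpolation when grids differ),
restricted to 220–320 nm, scaled so its maximum is exactly +1. A
non-positive maximum is an error (normalisation undefined), not a silent
sign flip.

**Estimator bias under noise.** The |dA/dT| peak of a two-state transition
with |ΔH| ≈ 40 kcal/mol varies by < 0.3% over ±2 °C around Tm, so
single-replicate estimates under 1% amplitude noise jitter by ~1.5 °C;
the estimator is unbiased, and triplicate averaging over a seed sweep
recovers the midpoint to well under 0.5 °C. On noise-free curves, recovery
is exact to < 0.1 °C for |ΔH| from 20 to 80 kcal/mol on a 1 °C grid.

## CD titration fitting

The ellipticity at 288 nm (the positive i-motif band) versus pH is fitted
to a four-parameter Hill sigmoid θ(pH) = θ_u + (θ_f − θ_u)/(1 +
10^{n_H(pH − pH_T)}) by Levenberg–Marquardt least squares
(`scipy.optimize.curve_fit`). The published method states only "inflection
point of fitted ellipticity"; the Hill form with a free slope is this
package's choice, with the slope bounded to (0.2, 10] to exclude
degenerate step fits. Initialisation: baselines from the 10% extreme-pH
quantiles, pH_T from linear interpolation of the half-amplitude crossing,
n_H = 1. pH_T_SE is the square root of the corresponding covariance
diagonal. A fit whose amplitude does not exceed 3× the residual noise is
rejected, and a fitted pH_T outside the sampled span is flagged as
extrapolated. The single-wavelength fit mirrors the stated method; no
global multi-wavelength fitting. Blank subtraction is assumed already
applied upstream.

On the standard 13-point grid (pH 5.0–8.0, 0.25 steps) at 2% amplitude
noise, the fitted pH_T has RMSE < 0.05 across the 6.6–7.2 range and mean
bias < 0.02, and the covariance-derived SE tracks the seed-to-seed scatter
within a factor of 2 — consistent with the ±0.01–0.08 SEs typical of such
fits.

CD spectra are classified by band signature on a Savitzky–Golay-smoothed
scan: a positive peak in 285–292 nm plus a negative trough in 255–270 nm
is `i_motif`; a positive peak in 260–268 nm plus a trough in 235–245 nm is
`parallel_g4`; anything else (including flat scans) is
`unfolded_or_other`. Peaks need 5% of-range prominence, so noise ripples
do not classify.

## Bisulfite clone analysis

**Alignment.** Each clone is globally aligned to the reference
(C-rich-strand frame) with affine gaps via Biopython's `PairwiseAligner`:
match +1, mismatch −2, gap open −5, gap extend −1, end gaps penalised
(clones are full-length PCR products). In bisulfite mode the substitution
matrix is asymmetric: (ref C, read T) scores as a match, so conversions
are never forced into gaps and a (C,T) column never scores worse than
(C,C). The gap penalties deliberately favour one contiguous deletion over
scattered small gaps, matching the single-block deletions seen in cloned
isolates. Both the clone and its reverse complement are aligned and the
higher score kept, so cloning orientation need not be resolved upstream.
When a deleted segment is flanked by identical bases, equal-scoring gap
placements exist; the aligner's deterministic traceback picks one, and
callers should treat called intervals as equivalent up to such shifts.

**Conversion calling.** Over all reference-C columns in scope (one
element, or the whole region): frequency = (C,T)/((C,T)+(C,C)). Columns
with the C under a read gap or read as A/G are excluded from the
denominator and tallied separately. Both an element-scoped and a
read-scoped mean conversions-per-clone are reported, because a published
per-36mer mean can include flank cytosines and the two denominators
differ.

**Deletion calling.** Maximal gap-in-read runs of ≥ 2 bp become events
(1 bp gaps are ambiguous with sequencing artifacts; the threshold is
configurable to 1). Events are classified against an element [s, e) with a
flank window (default 50 bp, since "near the 5′ end" has no published
distance): UPSTREAM_5P (wholly in [s−w, s)), OVERLAP_5P (straddles s),
INTERNAL, OVERLAP_3P (straddles only e), DOWNSTREAM_3P (wholly in
[e, e+w]), else OUTSIDE. The classes partition events, and changing the
window only moves events between the flank classes and OUTSIDE. The
deletion frequency counts clones with ≥ 1 event in {UPSTREAM_5P,
OVERLAP_5P, INTERNAL} — the 5′-associated geometry observed for
i-motif-linked deletions.

## Mass-shift analysis

Average residue masses (dA 313.21, dC 289.18, dG 329.21, dT 304.20, dU
290.17 Da) with −61.96 Da for the 5′-OH terminus (synthetic oligo
convention; a 5′-phosphate adds 79.98 Da). Average rather than
monoisotopic masses because ESI deconvolution of 36mers reports average
neutral mass. Each dC→dU conversion adds Δm = 0.984 Da (the "1 Da" shift
at nominal precision); a peak is assigned count k = round((m − m_ref)/Δm)
when the residual is within tol = 0.35 Da (below Δm/2, so assignment is
unambiguous). Frequencies are abundance-weighted and sum to 1 over
assigned species; the intact fraction is the abundance share at masses
≥ m_ref − tol, with sub-reference peaks treated as strand-breakage
fragments. The distribution mode breaks ties toward smaller k.

## Deletion-risk model and length profile

Impairment probability is 1 − (1 − p)^c, evaluated as
−expm1(c·log1p(−p)) for stability at small p; defaults p = 0.05, c = 25
(printed result 0.72). The length profile stores, per locus, repeat copy
number, in-vitro pH_T and Tm, and the deletion fraction among cloned
isolates. The association is summarised by a Spearman rank correlation
(ties mid-ranked) — chosen because the claim is monotone and the sample
small — reported descriptively, without a headline p-value; a constant
column returns an explicit `None` sentinel, never a silent 0. The
threshold check verifies that every locus with pH_T above the cutoff
(default 7.0) has deletion fraction exactly 1.0. In the bundled profile
the BCR locus stores a deletion count (1) rather than a fraction because
no denominator was published, and the ABL1 pH_T carries provenance
"figure" (plateau value, not a printed number); incomplete rows are
dropped from the association (≥ 4 complete rows required).

## Synthetic data: what it emulates, and what it does not

All generators draw from one explicit seeded `numpy` Generator per call
(replicates use per-replicate child streams); identical seeds give
byte-identical output, and planting records are returned as test oracles.

* **Melt curves** — two-state folding with linear baselines:
  A(T) = (1−α)·b_f(T) + α·b_u(T). The fraction unfolded is the
  *linearised* van't Hoff logistic α(T) = 1/(1 + exp[(ΔH/(R·Tm_K²))(T −
  Tm)]), ΔH < 0 (folding exotherm), which keeps α(Tm) = ½ and the exact
  van't Hoff slope |ΔH|/(4R·Tm_K²) at the midpoint while being symmetric
  in T. The exact 1/T form places the |dA/dT| extremum ~2R·Tm²/|ΔH| K
  below Tm (≈ 0.3 °C at ΔH = −40), which would make "the first-derivative
  estimate of a curve generated at Tm" systematically disagree with Tm;
  the symmetric form makes the generated midpoint and the estimator's
  target coincide, which is the property the recovery analyses need.
  Default ΔH −40 kcal/mol, folded baseline 1.0, unfolded 0.7 (hypochromic
  at 295 nm), grid 4–95 °C at 1 °C (the 0.5 °C/min ramp sampled every
  1 °C). Hysteresis is emulated by giving annealing curves their own lower
  midpoint — no folding-kinetics model is attempted.
* **Titrations** — the same Hill sigmoid the fitter assumes, grid pH
  5.0–8.0 in 0.25 steps, defaults θ_f = 6, θ_u = 0.5 mdeg, n_H = 1.5,
  noise ~ N(0, (noise_sd·amplitude)²). Because generator and fitter share
  the model, recovery tests demonstrate estimator correctness, not
  model adequacy for real CD data.
* **Clone sets** — each clone is the reference with planted deletion
  intervals excised, then every surviving C independently converted with
  the probability of its structural state. Default rates (C:C⁺ 0.35,
  protonated single-strand 0.45, duplex 0.01, neutral single-strand 0.05)
  honour the frontier-orbital reactivity ordering dC⁺ > C:C⁺ ≫ C:G > dC,
  with the C:C⁺ value on the scale observed at a long genomic repeat; all
  are overridable. Published work does not state clones per region;
  fixtures default to 27 (the scale of the published alignments) and are
  configurable. No sequencing-error or chimera model.
* **Peak lists** — per-molecule conversion counts k ~ Binomial(n_C, p);
  species k at m_ref + k·Δm with count abundances; optional fragment peaks
  (three, at 0.35/0.55/0.8 × m_ref) carrying exactly the requested share
  of total abundance. At the documented 5000-molecule scale the empirical
  mode of Binomial(27, 0.33) equals the analytic mode 9 in ~78% of seed
  draws (pmf(8) = 0.1548 vs pmf(9) = 0.1610), which is why reproduction
  fixtures pin their seed.
* **Genomes** — uniform random background with exact planted repeats;
  adjacent random bases can occasionally extend a planted run, so oracle
  tests compare scanner output against brute-force enumeration of the
  same sequence rather than against the planting record alone.

These generators reproduce the statistical structure the analyses assume —
not instrument line shapes, chromatography, CD band shapes, or sequencing
chemistry. Passing recovery tests therefore validates the estimators and
callers, not the physical models of real instruments.

## Problem sizes and reproducibility

The bundled reproduction workflow uses 3×13-point titrations, 92-point
melt curves, 500 clones × 200 bp references (conversion), 27-clone
deletion fixtures, and 5000-molecule peak lists — sizes chosen to give
each estimator enough data to meet its stated tolerance while keeping the
whole workflow in seconds. `scripts/acceptance.py` and `imotifkit
reproduce` are deterministic for a fixed seed; fixture seeds documented as
part of the study conditions are fixed, and everything else derives from
the user seed through named child streams.

## Known limitations

* The genome-wide element census runs on any supplied FASTA but ships
  with no assembly, so no genome-wide count is claimed.
* The Hill-sigmoid titration model and the two-state melt model are
  emulation choices; real curves with sloping baselines, aggregation or
  multi-step transitions need model extensions.
* Deletion calling reports gap runs from one deterministic optimal
  alignment; interval boundaries are defined up to equal-scoring gap
  placement within repeated flanking bases.
* The suppression model treats replication cycles as independent
  Bernoulli trials with constant p; it estimates nothing from data.
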