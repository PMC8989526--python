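# imotifkit

Tools for analysing **i-motif-forming d(TCCC)n repeats** and their link to
spontaneous 5′-oriented deletions in the human genome.

In regions of GC skew, the C-rich strand of a d(TCCC)n repeat can fold into
an i-motif — a four-stranded structure held together by hemiprotonated
C:C⁺ pairs — while the complementary d(GGGA)n strand can fold into a
G-quadruplex. G-quadruplexes form at physiological pH whenever n > 3, but
i-motif stability is strongly length dependent: the transitional pH
(pH_T, the pH at which half the molecules are folded) rises with n and
exceeds 7 once n ≥ 9. In repair-compromised cells, deletions at these loci
track the i-motif, not the G-quadruplex: they sit 5′ of the repeat on the
C-rich strand, often extend into it, and reach 100% of cloned isolates
exactly where pH_T > 7. `imotifkit` packages the full analysis chain behind
that argument, with seeded synthetic-data generators standing in for the
raw instrument and sequencing data, so every stage is testable end to end
with no downloads.

## What is in the box

| module | purpose |
|---|---|
| `imotifkit.repeats` | scan FASTA for d(TCCC)n/d(GGGA)n elements (BED6 out), flag folding competence, annotate oligo-dC runs against the (4n−1) rule |
| `imotifkit.melting` | first-derivative Tm/Ta and hysteresis from A295 melting ramps; normalised thermal difference spectra |
| `imotifkit.titration` | fit ellipticity-at-288 nm vs pH to a Hill sigmoid for pH_T ± SE; folded-fraction prediction; CD signature classification |
| `imotifkit.bisulfite` | global alignment of cloned bisulfite isolates (C→T scored as match), conversion-frequency and 5′-deletion calling per element |
| `imotifkit.massdist` | oligonucleotide average masses; dU-count assignment of deconvoluted neutral-mass peaks on the +0.984 Da ladder |
| `imotifkit.deletion_model` | suppression-failure probability 1−(1−p)^c; length/pH_T/deletion-fraction profile association (Spearman) |
| `imotifkit.synthetic` | seeded generators for every input type (melt curves, titrations, clone sets, peak lists, genomes) |
| `imotifkit.tables` | bundled in-vitro reference tables (Tm/Ta/hysteresis/pH_T by repeat length) |
| `imotifkit.pipeline` | end-to-end reproduction workflows |

A `imotifkit` command-line tool exposes each stage
(`simulate`, `scan`, `melt`, `tds`, `titrate`, `classify-cd`, `bisulfite`,
`massdist`, `risk`, `profile`, `reproduce`).

## The core quantities

* **pH_T** — inflection of θ(pH) = θ_u + (θ_f − θ_u)/(1 + 10^{n_H(pH − pH_T)}),
  fitted by nonlinear least squares to the 288 nm CD band; folded fraction
  f(pH) = 1/(1 + 10^{n_H(pH − pH_T)}), so f(pH_T) = ½.
* **Tm, Ta, hysteresis** — temperatures of maximal |dA₂₉₅/dT| on heating and
  cooling ramps (local-quadratic smoothing, parabolic sub-grid refinement);
  hysteresis = Tm − Ta reports slow folding kinetics.
* **Conversion frequency** — among aligned reference-C columns,
  (C→T)/((C→T)+(C→C)); bisulfite attacks cytosines that are not
  Watson–Crick paired (reactivity dC⁺ > C:C⁺ ≫ C:G > dC), so native-DNA
  conversion reports non-B structure.
* **Deletion frequency** — fraction of clones with a ≥2 bp gap run
  upstream of, overlapping the 5′ boundary of, or inside a repeat element.
* **dU distribution** — peaks at reference mass + k·0.984 Da give the
  per-molecule conversion count k; its mode and the intact fraction
  summarise the spectrum.
* **Impairment probability** — P(an unsuppressed i-motif impairs
  replication at least once in c cycles) = 1 − (1 − p)^c.

## Worked example

```bash
$ imotifkit risk --p 0.05 --cycles 25
0.7226
```

With a per-cycle escape probability of 0.05, an i-motif site has a 72%
chance of impairing replication at least once in 25 cycles — the
back-of-envelope argument for deletion accumulation in long-cultured cells.

```bash
$ imotifkit reproduce --seed 1
{
 "seed": 1,
 "ph_t_recovered_tccc9": 7.10036490870347,
 "ph_t_recovered_tccc5": 6.7065818375627995,
 "tm_recovered_ph65_c": 40.70130829893063,
 "tm_recovered_ph53_c": 66.70095755837411,
 "conversion_pct_tccc9": 37.1925925925926,
 "deletion_pct_upstream": 18.51851851851852,
 "deletion_pct_overlap": 100.0,
 "du_mode": 9,
 "intact_pct": 92.0,
 "impairment_probability": 0.7226104268781659,
 "profile_spearman_rho": 1.0,
 "profile_threshold_consistency": true
}
```

Reading the summary: titrations generated with true pH_T 7.1 and 6.7 (2%
noise, 3 replicates) re-fit to 7.100 and 6.707; noise-free two-state melt
curves generated at 40.7 °C and 66.7 °C are recovered to 0.001 °C by the
first-derivative estimator; 500 synthetic clones converted at 37.4% per
element cytosine are called at 37.2%; the 27-clone deletion fixtures yield
exactly 18.5% (5/27) and 100%; the binomial dU peak list has modal count 9
with 92% of abundance at or above the reference mass; and the bundled
length profile is perfectly rank-concordant (ρ = 1) with every
pH_T > 7 locus deleted in all clones.

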