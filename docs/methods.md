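# Methods

This note records the models, conventions and numerical choices behind
`idrkit`, and what the synthetic-data validation does and does not
demonstrate.

## Sequence records and coordinates

All scanning operates on `ProteinRecord`s: an uppercase sequence over the
twenty canonical letters (X/U/B/Z tolerated on input) plus a
`numbering_offset`, the full-protein residue number of the first stored
residue.  Every run, hit and profile is reported 1-based and inclusive in
full-protein numbering, so a construct spanning residues 194–362 reports
its poly-A tract at 274–281, not 81–88.  Ambiguous letters break
homopolymer runs and are excluded from charge, composition, hydropathy and
entropy statistics (numerator *and* denominator), which keeps the twenty
single-residue composition fractions summing to exactly 100%.

## Windowed profiles

Hydropathy uses the Kyte–Doolittle scale with a centred moving average
(window 9 by default, odd windows only).  Positions whose full window does
not fit the sequence carry NaN rather than a shrunken window: shrinking
biases edge values toward single-residue noise, and NaN keeps profile
lengths equal to sequence lengths.  The low-complexity proxy is the
Shannon entropy (bits) of the residue composition of each sliding window
(default 12), indexed by window start.  It is a proxy: the segmentation
algorithms used for formal low-complexity calls are iterative and
parameterized, and are deliberately not reimplemented here.

## Charge and the charge–hydropathy plane

Formal net charge is (#K + #R) − (#D + #E) with histidine neutral and
termini ignored — the convention under which a construct is usually
described by residue counts.  A His-positive variant is available for
acidic-pH reasoning (`ChargeConvention(histidine_positive=True)`); note
the packaged Musashi-1 construct contains two histidines, so the variant
reports +4.  The charge–hydropathy classifier places a protein at
(⟨H⟩, ⟨R⟩) — mean min–max-scaled hydropathy and mean absolute net charge
per residue, both composition-only statistics — and classifies it against
the standard empirical separator ⟨R⟩ = 2.785⟨H⟩ − 1.151.  The line is
config (slope/intercept), because published analyses vary in its exact
placement.  Tie rule: a point exactly on the line classifies
`disordered_like`; the boundary belongs to the disordered half-plane.

## Motif definitions

The literature names motif classes without formal definitions, so the
scanner's definitions are explicit config (`MotifConfig`):

- `SR_repeat`: ≥ 2 consecutive SR or RS dipeptides (a single SR is just a
  dipeptide, not a repeat);
- `RG_RGG`: an RGG tripeptide, or an isolated RG flanked by glycine;
- `GS_Y_GS`: `[GS]Y[GS]` by default.  The aromatic position is
  configurable to `[FYW]`, the broader class reported in other RBP IDRs;
  the default stays tyrosine-only because that is the class the Musashi-1
  region is stated to lack — and indeed the broader pattern *does* match
  once in the construct (GFG at 343–345), so the two classes are genuinely
  different claims and are kept distinct;
- `QN_rich`: any 10-residue window with ≥ 6 Q/N; overlapping qualifying
  windows merge into one maximal hit.

Hits are non-overlapping within a class (left-to-right maximal matching)
and may overlap across classes.

## Polyalanine census

Each protein contributes its maximal alanine run.  Two binning modes ship
because database substring searches and per-length bar charts imply
different semantics: `exact_max_run` (default) assigns each protein to the
single bin of its longest run, so the bins plus the <5/>20 remainder
partition the proteome; `at_least` counts a protein in every bin up to its
longest run, giving counts that are non-increasing in k.  The positive
label is a configurable keyword policy: `rna_related` (any annotation term
containing "RNA", case-insensitive substring) or `rna_binding` (exact term
"RNA binding").  The exact keyword lists used in published censuses are
not public, so the policy is explicit, serialized config rather than a
hidden constant.  Enrichment is proportion[k] / background, background
taken over the whole (deduplicated) proteome; accessions with isoform
suffixes ("-2") collapse to the canonical accession by default.
Uncertainty: protein-level percentile bootstrap, B = 1000, seed mandatory.
Bins empty in more than half the resamples report NaN intervals.

## Secondary shifts and helical populations

Δδ = δ_obs − δ_coil per residue and atom (Cα, Cβ, C′), against a packaged
random-coil reference table compiled from the disordered-protein
random-coil literature.  Sequence identity between the shift table and the
record is checked per position and mismatches raise with the offending
residue number.  Neighbor, temperature and pH corrections to the coil
reference are *off* by default: the package does not ship correction
coefficient tables, and which corrections a given study applied is rarely
stated; a custom reference table (e.g. with corrections pre-applied) can
be passed in their place.  The helical-population estimator is the
simplest defensible one: mean(Δδ_Cα over region)/2.8 ppm, clipped to
[0, 1], requiring ≥ 3 defined residues.  2.8 ppm is the conventional
full-helix Cα offset.  This two-state estimator ignores β/PPII content and
neighbor effects; multi-state chemical-shift deconvolution is out of
scope, so its outputs should be read as first-order population scales, not
replacements for dedicated secondary-structure-population software.

## Intensity ratios and broadening flags

Ratios I_high/I_low are computed only where both intensities are positive;
censored residues are skipped and counted, and means (overall and over
named regions, defaults helix1 = 208–218, helix2 = 270–284) are arithmetic
means of per-residue ratios.  The molar ratio of the two concentrations is
reported alongside as the ideal-dilution reference.  Broadening flags mark
residues with ratio < f × molar ratio (default f = 0.5, a deliberately
coarse screen) and merge consecutive flagged residue numbers into regions.

## R₂ fitting and Monte-Carlo errors

Per residue, I(t) = I₀·exp(−R₂t) is fitted by nonlinear least squares
(scipy `curve_fit`), initialized at I₀ = I(t₁) and
R₂ = log(I(t₁)/I(t_last))/(t_last − t₁) clipped to ≥ 0 — a derivative-free
start that is within the convergence basin for any monotone decay.  The
default delay grid is 17.2, 34.3, 51.5, 68.6, 120.1, 154.4 ms.  Errors
come from a Monte-Carlo procedure: the observed points are perturbed
n_mc = 500 times by Gaussian noise at the per-point noise level and refit;
`sd_R2` is the standard deviation and (`r2_lo`, `r2_hi`) the 2.5/97.5
percentiles of the refitted rates.  The noise level is taken from the
series' noise estimate when supplied (scalar, per-residue, or per-point);
otherwise it is estimated per residue from the fit-residual RMS.  When a
noise estimate is supplied the least squares is weighted by it.  Fits that
fail to converge flag the residue (`converged=False`) without aborting the
table.  Calibration, measured on synthetic decays with 2% multiplicative
noise, gives 95% interval coverage of ~94–96% across seeds — consistent
with nominal given binomial noise at 200 residues per replicate, which is
why the acceptance test pools three independent 200-residue replicates
before asserting the 93–97% band.

## CD conversion

Δε = θ·0.1·MRW/(l·C·3298), applied pointwise over a wavelength series with
no smoothing.  MRW is (Σ residue masses + one water)/n from a packaged
average-mass table; a single glycine therefore reports 75.07 Da.  Whether
a purification tag is included in MRW is the caller's choice of input
sequence; the packaged construct excludes tags.

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of (spec, seed); identical seeds give
byte-identical outputs.

**Proteome.**  Lengths are lognormal (median ≈ 370 residues), residues
i.i.d. from human-proteome-like frequencies, so alanine runs ≥ 5 arise by
chance at a realistic, very low rate (~5·10⁻⁴ per 300-mer).  Poly-A tracts
of specified lengths are inserted at positions whose flanks are not
alanine, so planted runs are maximal and exact; the truth table records
the *realized* maximal run per protein.  Annotation labels are Bernoulli
at 20.3% background — the proportion of RNA-related entries in the curated
human proteome — multiplied by the planted enrichment factor (default 2.0
at lengths 5–10, echoing the reported RNA-binding enrichment for short
tracts).  Defaults: 2000 proteins, 40 planted per length.  Not emulated:
residue autocorrelation, domain structure, GC-content-driven codon
effects, annotation noise, or the coupling between length and annotation
that real proteomes show.  Recovery tests therefore demonstrate that the
census measures what it defines on data satisfying its sampling
assumptions — not that real-database estimates are unbiased.  One known
feature of the design itself: because planted positives also raise the
proteome-wide background, the measured enrichment of a planted 2× positive
rate is slightly below 2 (≈1.7–1.8 at the default planting fraction); the
recovery criterion is therefore CI coverage of 2.0, not point equality.

**Shifts.**  δ = δ_coil + p·Δδ_full + N(0, σ) with full-helix offsets
(Cα +2.8, Cβ −0.5, C′ +1.1 ppm) over configured segments; glycine emits no
Cβ.  With σ = 0.1 ppm over a 15-residue helix the population estimator's
standard error is ≈ 0.01, far inside the ±0.05 recovery tolerance.

**Decays.**  I(t) = I₀·exp(−R₂t)·(1 + ε), ε ~ N(0, 0.02), R₂ ~ U(5, 30) s⁻¹,
with the per-point noise estimate (0.02 × observed intensity) attached to
the series, as an experimentalist would attach a spectral noise floor.

## Problem sizes and runtimes

The default validation sizes — 2000-protein proteome with B = 1000
bootstrap resamples, 200 relaxation curves × 500 Monte-Carlo refits, 1000
random sequences for oracle equivalence — were chosen so the full test
suite and the acceptance script each complete in about a minute on a
single CPU while keeping every statistical check's standard error well
inside its tolerance band.

## Known limitations

- The motif and keyword definitions are field conventions made explicit,
  not reconstructions of any specific study's unpublished configuration;
  conclusions that depend on them should report the config used.
- The helical-population estimator is two-state and Cα-only.
- Random-coil corrections (neighbor/temperature/pH) require a
  user-supplied reference table.
- The census treats annotations as ground truth and proteins as
  exchangeable; no phylogenetic or family-level de-correlation is applied.
- NMR-STAR ingestion is not implemented; shift tables are plain TSV.
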