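# Methods

`apcscreen` implements a G1 chemical-proteomics screen for substrates of
the APC/C ubiquitin ligase acting with its co-activator Cdh1.  The
experimental logic it models: G1-arrested cells are treated with APC/C
inhibitors or vehicle; proteins whose abundance rises under inhibition are
candidate substrates; candidates are then required to carry a plausible
APC/C degron (D-box or KEN-box) in an accessible (disordered) region of an
intracellular, non-secreted protein.  A companion high-content assay
measures the mitotic fraction of a cell population from the maximum
DNA-stain intensity of each nucleus.

## Quantification model (psm layer)

Input is a PSM-level table: peptide sequence, candidate protein
identifiers, target/decoy flag, peptide posterior probability, and
per-channel TMT reporter signal-to-noise (S/N) for a 10-plex design
(default layout: 3 t0 + 3 control + 3 treated channels and one bridge
channel that is carried through quantification but excluded from
statistics).  The chain is:

1. **Low-signal exclusion.**  PSMs with summed S/N below 100 across
   channels are dropped.  The boundary is inclusive on the keep side
   (a sum of exactly 100 is retained).  By default filtering happens on
   raw, instrument-scale S/N *before* normalization, because the floor is
   an instrument-scale quantity; the order is config-overridable since
   the processing description leaves it ambiguous.
2. **Column normalization.**  Each channel is multiplied by
   (mean of raw channel totals)/(that channel's total), the equal-loading
   correction.  Afterwards all channel totals are equal to machine
   precision.  The target scale (the mean of totals) is arbitrary; the
   mean keeps values on the input scale.
3. **Protein probability.**  The product of per-peptide posterior
   probabilities (best posterior per distinct peptide sequence), computed
   in log space.  This is also the protein score used for FDR control,
   since no other protein-level score is defined by the procedure.
4. **Picked protein FDR (1%).**  Targets and decoys are paired by base
   identifier (`decoy_` prefix); only the higher-scoring member of each
   pair survives; survivors are ranked by descending score; FDR at a
   cutoff is `#decoys >= cutoff / #targets >= cutoff`, with ties sharing
   the counts at the end of their tie block; q-values are monotonized
   from the bottom of the ranking; targets with q <= 1% are accepted.
5. **Parsimony inference.**  Accepted identifications are collapsed to a
   minimum protein set covering all peptides: exact minimum set cover per
   ambiguity group of up to 12 candidate proteins (ties broken by the
   lexicographically smallest protein tuple), greedy cover beyond that
   (within the usual `ln n + 1` factor).  Each shared peptide is assigned
   to exactly one retained protein — the candidate with the most distinct
   peptides, ties lexicographic.
6. **Relative abundance (RA).**  Per protein, channel values are summed
   over its assigned PSMs and the vector is rescaled to sum to 100.
   RA is therefore invariant to any global rescaling of the input.

## Differential screen

Fold change is mean(treated RA)/mean(control RA).  Significance is a
two-tailed, unpaired Student's t-test with pooled variance
(df = n1 + n2 − 2) on the untransformed RA replicates; a log2 option
exists but is off by default because the screen's stated test operates on
measured abundances.  A zero pooled variance raises a distinct error
rather than returning p = 0.  Because the per-protein RA rescaling is a
common factor in both arms, t statistics are exactly invariant to it; the
null calibration of the screen is that of the underlying noise model.

The fold-change cutoff is **calibrated**: it is the median fold change of
the previously reported substrates detected in the same run (the
`known_substrates` input), so the cutoff inherits the run's effective
sensitivity.  The screen keeps proteins with fc >= cutoff (inclusive),
more than one distinct peptide, and p < 0.05 (strict).  No
multiple-testing correction enters the screen decision; a
Benjamini–Hochberg q-value column is emitted for the user only.

**Power analysis.**  For each protein the continuous observations per
group needed to detect a 15% change at alpha = 0.05 and power = 0.95 is
solved from the two-sample, two-sided noncentral-t power equation at
effect size d = 0.15·mean/sd, with sd the pooled within-arm standard
deviation of RA values.  The solution is continuous (no rounding) and
floored at n = 2.  The normal-approximation formula
2(z_{0.975}+z_{0.95})²/d² agrees in the moderate-d (large-n) regime but
substantially underestimates n for large d, where the exact noncentral-t
solution (cross-checked against `statsmodels` and Monte-Carlo power) is
the correct one.

**Knockout intersection.**  Proteins "changing significantly by more than
20% in both knockout clones" are those with p < 0.05 in both comparisons
and fold change < 0.8 in both (decreased) or > 1.2 in both (increased) —
symmetric on the linear scale of the stated rule, not on the ratio scale.

## Degron scanning

Motif classes: minimal D-box `RxxL` (length 4), extended D-box
`RxxLxxxxN` (length 9), KEN-box `KEN` (length 3).  The scanner reports
every occurrence, overlapping and nested ones included, with 1-based
inclusive coordinates; a minimal D-box coinciding with the first four
residues of an extended D-box is flagged `nested_in_ext` rather than
removed.  Unknown residues (`X`) never satisfy anchored positions.  The
ABBA motif has no settled consensus and ships only as a registration hook
(`register_motif_class`).

**Similarity score.**  Hits are scored against an alignment of reference
degron sequences with a position weight matrix (pseudocount 1, uniform
1/20 background); the log-odds sum is min-max normalized so the
best-scoring reference sequence maps to 1 and the worst possible sequence
to 0, clipped to [0, 1].  The packaged reference alignment
(`data/reference_degrons_synthetic.tsv`) is a small consensus-derived
*synthetic* stand-in, suitable for the simulators and tests; production
scans should substitute a curated alignment of validated degrons.  Note
that the KEN motif is fully anchored over its three residues, so with a
motif-length alignment every KEN hit scores 1.0 — flank-aware scoring
would require a longer alignment window, which the hit contract here does
not use.

**Consensus class** is derived from the similarity score (high >= 0.9,
medium >= 0.75, low otherwise, overridable); the upstream tool treats it
as an independent categorical output whose exact boundaries are not
published, and deriving it from the same score keeps the filter
implementable.

**Filters.**  A hit passes iff similarity >= 0.75, consensus class medium
or high, mean per-residue disorder over the span >= 0.4 (all boundaries
inclusive), and the protein is intracellular and non-secreted.  Disorder
tracks are inputs; a built-in composition heuristic (windowed fraction of
disorder-promoting residues) exists as a clearly non-equivalent fallback.
Proteins missing from the localization table are assumed intracellular
and non-secreted, with a warning.

## Candidate nomination

A protein is nominated iff it passed the differential screen and has at
least one passing D-box (minimal or extended) or KEN hit.  Candidates are
grouped as D-box only / KEN-box only / both, sorted within groups by
descending fold change, and annotated with the best-scoring passing hit
per class (an `all_hits` flag reports every passing hit's scores,
slash-joined).  The nominated set is asserted to be a subset of the
screen-passing set, itself a subset of the quantified set, on every run.
The run manifest records the calibrated threshold actually used, row
counts per stage, parameters, and timings.

## Mitotic fraction

Per-nucleus maximum intensities are pooled across wells per condition.
The intensity threshold is derived from the control condition — by
default its 0.99 quantile (linear interpolation), a reproducible stand-in
for the traditional manual setting; fixed and two-component log-normal
mixture-split methods are available, and the method used is recorded.
The mitotic fraction is the fraction of cells *strictly above* the
threshold.  Cumulative frequency curves are empirical CDFs
(right-continuous, reaching 1 at the maximum observation).  Optional
image-based measurement segments nuclei as connected components above a
global Otsu threshold computed on log intensity (fluorescence images are
background-dominated and nuclei span a wide brightness range, so raw-scale
Otsu can split dim from bright nuclei instead of background from
foreground), with configurable area bounds, and reports each nucleus's
maximum pixel value.

## Synthetic-data generators

All generators are pure functions of their configuration; the seed fixes
every random draw, so identical calls are byte-identical.

**TMT simulator.**  Each PSM's channel S/N is `base_intensity ×
protein abundance × peptide share × arm fold-change × multiplicative
lognormal noise` with the configured CV (S/N is positive and
right-skewed, hence lognormal; CV = 0 gives exact values).  Protein
abundances are lognormal (sigma 1), peptide shares lognormal (sigma 0.5),
peptides per protein 1 + Poisson with mean 4 per protein — a realistic
depth for a deep TMT run, under which ~5% of proteins are single-peptide
and correctly excluded by the >1-peptide rule.  Because equal peptide
mass is loaded per channel, planted fold changes act on the *relative*
scale: regulated proteins gain their fold change in the treated arm and
all unregulated proteins are diluted by a common factor (recorded as
`loading_dilution`) so expected channel totals are equal.  At CV = 0 the
treated/control ratio of a regulated protein equals its true fold change
exactly, both in the raw table and through the quantification chain
(up to PSMs removed by the S/N floor, a < 0.1% effect).  Two regulated
groups exist: novel substrates with log-uniform fold changes in
[1.15, 3.6] (the observed substrate range), and previously reported
substrates with lognormal fold changes around a median of 1.15 — the
calibration statistic of the study design — at a fraction of 0.5% of the
proteome (tens of knowns among thousands quantified).  A *null screen*
sets both regulated fractions to zero.  Decoy PSMs (default 10% of PSMs)
point at `decoy_`-prefixed identifiers and draw low posteriors
(Beta(2, 8)) versus high target posteriors (Beta(40, 1)); a configurable
5% of peptides are shared between two proteins to exercise parsimony.

**Proteome simulator.**  Random sequences with uniform residue
frequencies; planted motifs are placed at non-overlapping positions, with
the disorder track drawn uniform below 0.4 outside planted spans and in
[0.55, 0.95] inside them, so planted degrons always clear the disorder
filter and background regex matches almost never do.  The combined screen
dataset plants exact reference degron instances (similarity 1.0) in every
regulated protein and in a 10% background of unregulated proteins.

**Nuclei simulator.**  Interphase and mitotic maximum intensities are
lognormal (medians 2000 and 9000 AU, sigmas 0.25 and 0.2 — a ~4.5-fold
condensation brightening with realistic spread); exactly
`round(fraction × n)` cells per condition are mitotic.

### What the generators do not emulate

Chromatographic fractionation, isotopic interference and ratio
compression, peptide-specific ionization efficiency, missing channels,
batch effects across plexes, correlated disorder structure, and real
degron sequence diversity.  Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated noise
model, not that the biological conclusions of any particular screen are
reproduced.

## Problem sizes and numerical choices

Simulation-based checks use 2,000-protein null screens over 10 seeds
(pooled type-I error within 3 binomial SE of 0.05), 1,000-protein
recovery screens with 250 regulated proteins per planted fold change
(median within 5%), 400-protein end-to-end datasets with 20 planted
substrates over 10 seeds (sensitivity >= 0.9, false nominations among
degron-free unregulated proteins <= 1%), and 2,000 nuclei per condition
(fractions within 3 binomial SE).  Exact set cover is attempted up to
12-protein ambiguity groups; q-values use tie-aware counts; the power
equation is solved by bisection (`brentq`, xtol 1e-9) with the power
function clamped where extreme noncentrality overflows the
noncentral-t CDF.  Degenerate inputs (empty tables, zero-total channels,
zero variance, flat images, empty reference alignments) raise typed
errors or return empty results as documented on each function.

## Known limitations

* The similarity score is a PWM reimplementation, not the upstream
  tool's; absolute scores are not comparable across reference sets.
* Raw-file processing (database search, PSM rescoring) is out of scope;
  posteriors are inputs.
* The greedy set-cover path (ambiguity groups > 12 proteins) can be
  suboptimal by the standard logarithmic factor.
* The disorder heuristic is compositional and should not gate real
  biological decisions.
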