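# Methods

## The inference problem

A protease knockout changes the steady-state peptidome in a characteristic
way: direct substrates of the lost enzyme accumulate, their processed
products deplete, and everything else is untouched.  Given label-free
peptide quantification tables from knockout and wild-type enteroendocrine
organoid lines, the pipeline calls differentially abundant peptides and
reads the enzyme's cleavage specificity off their termini.  The package
pairs this analysis with a generative model of prohormone processing so
the whole chain can be exercised against known ground truth.

## Processing model (simulator)

Each precursor is processed, after removal of its annotated signal
peptide, by four mechanisms applied in physiological order:

1. **Endoproteolysis** — cleavage immediately C-terminal to any dibasic
   pair (KK, KR, RK, RR).  Every eligible boundary fires independently
   with the enzyme's efficiency (default 1); each released fragment
   therefore ends with the pair that licensed it.  PCSK1 and PCSK2 are
   modelled as one redundant activity: endoproteolysis stops only when
   both are disabled.  Monobasic sites and sequence context beyond the
   dibasic pair are not modelled; a consequence worth knowing is that
   glucagon's internal `…LDSRR…` pair is cleaved in a complete digest, so
   intact glucagon only survives partial digestion — real convertases skip
   that site for contextual reasons outside this rule.
2. **Carboxypeptidase trimming** — C-terminal K/R removed one residue at a
   time until a non-basic terminus remains.  Each precursor is assigned to
   exactly one carboxypeptidase (CPB1: the SST/NPW/PPY stand-ins; CPE: all
   others).  In reality the two enzymes have overlapping repertoires in
   different cell populations; a single-compartment model with both active
   would let one silently compensate the other's knockout, so the
   partition is what makes single-knockout accumulation observable.  At
   full efficiency only the final trimmed species persists; intermediates
   appear only under partial efficiency.
3. **Amidation** — a C-terminal glycine exposed by trimming is removed and
   the new terminus flagged amidated.  An amidated terminus is a blocked
   substrate: amidated species legitimately end in K/R (the GLP-1-amide
   case) and are not trimmed further.
4. **DPP4** — removal of the N-terminal dipeptide when residue 2 is P or
   A; single-pass by default (iterative by configuration), matching the
   single-dipeptide substrate/product pairs the analysis looks for.

Ground-truth labels are defined at efficiency 1: a species present only in
the wild-type peptidome is *mature*, present only in the knockout is
*KO-accumulating*, present in both is *constitutive*.

## Measurement model

Species *i* in sample *s* has log2 abundance

    x_is = base_i + clone_c(i) + genotype shift + tech_is

with `base_i ~ N(20.5, 1.0)`, clone effects `N(0, 0.25)`, technical noise
`N(0, 0.5)` (the replicates in the mirrored design are technical, so the
0.5 spread is assigned to the replicate level), and a genotype shift of
−4 log2 applied symmetrically: KO-accumulating species sit 4 log2 below
base in wild-type samples (a trace-level intermediate), mature species 4
log2 below base in knockout samples.  The symmetry keeps per-sample totals
approximately balanced, so total-intensity normalization does not distort
fold changes.  Missingness is left-censored: the lowest `censor_quantile`
(default 0.1) of linear intensities is set missing.

Thirty unmappable background peptides emulate the non-hormone proteins of
a real search database.  The background size and base spread are chosen
together so that the depleted (trace) cells — about 11% of the matrix in
the knockout scenarios — exceed the censored fraction; the censored values
are then genuinely the trace-level species, which is the structure the
down-shifted imputation downstream assumes.  A larger background with the
same censor quantile would instead delete present-state values near the
detection limit and attenuate true fold changes.

The default design mirrors the study: one bulk and one clonal wild-type
line versus two knockout clones, three technical replicates each (12
samples).  BMP treatment enters only as a sample label.

What the generator does **not** emulate: retention time and spectra,
ionization efficiency and peptide detectability, monobasic convertase
sites, CPB1's broader residue tolerance, BMP-dependent enzyme regulation,
between-run alignment artifacts, or shared-peptide ambiguity across
precursors (fixture sequences are constructed so every species maps
uniquely).  Passing tests therefore demonstrate that the statistics and
specificity logic recover planted signals under this noise structure, not
that they overcome every pathology of real LC-MS data.

## Statistics

Pipeline order is fixed: total-intensity normalization → replicate-
completeness filter (kept iff observed in all replicates of ≥1 clone ×
BMP group) → log2 → per-sample left-shifted imputation
(N(μ_s − 1.8 σ_s, (0.3 σ_s)²), σ estimated with ddof 1) → pooled-variance
Student's t (Welch available by configuration) → permutation q-values →
z-scaling (population sd) and average-linkage Euclidean clustering of the
significant set.  Prohormone-level comparisons use a no-imputation mode
that drops incomplete rows and tests raw log2 values.

**Permutation FDR.**  One label assignment is drawn per iteration and
applied to all peptides; null |t| values are pooled across peptides.  For
peptide *i*, `q_raw(i) = (pooled tail count ≥ |t_i| / n_perm) /
(observed count ≥ |t_i|)`, clipped to [0, 1]; the reported q is the
minimum of `q_raw` over all thresholds at least as lenient as |t_i|, which
enforces monotonicity.  Ties count inclusively (≥) in both numerator and
denominator, making the estimate deterministic.  Random sampling draws
distinct non-identity assignments without replacement; when fewer distinct
assignments exist than requested (e.g. 3-vs-3, 20 splits), all are
enumerated with a warning.  Per-peptide permutation p-values are pooled
tail fractions, near-continuous and testable for uniformity.  The
estimator is validated by calibration (complete-null discovery fraction,
p-uniformity against exhaustive enumeration) rather than by matching any
specific software's internals, which are not published.

**Degenerate cases.**  Zero pooled variance with equal means gives
t = 0, p = 1; with unequal means, signed infinity and p = 0 (flagged by the
infinite statistic).  Constant rows z-scale to zeros and are flagged.
Logo frequencies are computed over non-gap observations only;
deduplication (identical 8-residue windows collapse) applies to logo
construction, while enrichment fractions and repertoires use the full
enriched set.  Position labels are signed (−4..−1 = P4..P1 upstream of the
boundary, +1..+4 = P1'..P4' downstream); for a C terminus, −1 is the
peptide's last residue.

## Targeted MS1

Elemental compositions come from standard residue formulas plus water;
amidation contributes −O +N +H, oxidation +O.  Isotopologue distributions
are convolutions of per-element natural-abundance vectors (pinned in
`ms1_targeted.ISOTOPE_ABUNDANCES` for bit-reproducibility), computed by
exponentiation-by-squaring with truncation to five isotopes — exact for
the retained prefix, then renormalized.  Detection requires
idotp ≥ 0.88 and, when a retention time is supplied, elution inside
89–91 min, both bounds inclusive; accepted ions are quantified as the sum
of the M..M+4 intensities and rejected ones are reported with abundance 0.
Peak-shape similarity and mass-error criteria are intentionally not
implemented: no thresholds exist for them, so the detection contract is
the two quantitative rules only.  Observed envelopes are consumed from
TSV; raw-spectrum extraction is out of scope.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| enzyme efficiency | 1.0 | probability/event | per mechanism, per rule |
| ko_log2_shift | 4.0 | log2 | present vs depleted state distance |
| log2_sd_technical | 0.5 | log2 | replicate-level noise |
| log2_sd_biological | 0.25 | log2 | clone-level noise |
| censor_quantile | 0.1 | fraction | left-censoring of linear values |
| base_log2_mean / sd | 20.5 / 1.0 | log2 | species base abundance |
| n_background | 30 | peptides | unmappable constitutive rows |
| n_perm | 250 | permutations | q-value iterations |
| q_cutoff | 0.05 | — | significance threshold |
| imputation downshift / width | 1.8 / 0.3 | sample sd | left-shifted normal |
| idotp threshold | 0.88 | — | MS1 acceptance |
| RT window | 89–91 | min | MS1 acceptance |

One global seed fans out to per-stage seeds via CRC32 of
`"<seed>:<stage>"`; identical configuration and seed reproduce every
output byte for byte.

## Problem sizes

The bundled registry holds the proglucagon precursor plus seven
constructed stand-in prohormones (~60–180 aa), yielding 60–75 peptide rows
× 12 samples per scenario; permutation testing uses the full 250
iterations, and the calibration study runs 20 independent null
simulations.  These sizes keep a complete run of the analysis scripts and
acceptance computation in the tens of seconds on one core while leaving
every statistical component at its production settings.

## Known limitations

* The seven non-proglucagon fixtures are synthetic stand-ins with
  realistic topology, not database sequences; conclusions about specific
  hormones' real peptide forms should use a user-supplied FASTA/feature
  table.
* The carboxypeptidase substrate partition is a modelling device; it makes
  CPB1's repertoire disjoint from CPE's, whereas the real enzymes overlap.
* The permutation-FDR estimator is conservative when true effects are
  dense, because permuted labels of effect peptides inflate the pooled
  null tail.
* Amidated peptides are matched through the amide-donor rule (successor
  glycine); other PTMs are carried through but not validated.
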