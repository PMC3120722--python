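# Methods

This note documents the models, parameter choices and numerical decisions
behind fluidprofiler, and what its synthetic benchmarks do and do not show
about real data.

## Homogeneity screen

### Model and procedure

The input is a proteins × patients matrix of label-free XIC intensities
with a per-protein identification score. Missing cells represent
non-detection of a protein in a sample.

1. **Missing values** are converted to 0 before any arithmetic. In
   label-free protein-level data, absence of an XIC signal predominantly
   reflects abundance below the detection limit, so zero is the least
   presumptuous fill; no imputation scheme is applied. (Parsing keeps
   missing as NaN — the zero policy belongs to the analysis, not the file
   format.)
2. **Total-sum normalization**: each patient column is scaled by
   `T(ref)/T(s)` so every column total equals the reference patient's.
   `reference="auto"` picks the patient whose total is closest to the
   median total, ties broken by column order — a neutral default when no
   patient is known to be technically cleanest. Post-normalization totals
   agree with the reference total to a relative 1e-9.
3. **PCA**: patients are observations, proteins mean-centered (not
   variance-scaled) variables; components come from the SVD of the centered
   matrix, retaining `min(n_patients − 1, n_proteins)` components.
   Intensities are analyzed on the raw scale by default; a `log10(x+1)`
   option exists for data whose dynamic range would otherwise let a handful
   of proteins determine the picture entirely. Component signs follow a
   deterministic convention (largest-magnitude loading positive).
4. **Distance**: each patient's first-two PC scores, each axis divided by
   its across-patient sample SD (ddof = 1), Euclidean norm. PCA scores are
   centered, so this is the distance from the sample mean in SD units. Two
   components are the default because the screen is read against 2-D score
   plots; a full-space distance and a pooled-SD variant (norm divided by
   the RMS of the per-axis SDs) are provided, since with per-patient data
   unavailable either standardization convention is defensible. A
   zero-variance axis contributes 0 with a warning.
5. **Subsampling**: B iterations, each drawing m proteins uniformly without
   replacement and running a self-contained PCA + distance on the
   sub-matrix; the report is the per-patient mean. Defaults m = 50,
   B = 1000. The PCA is recomputed per subsample rather than projecting
   onto the full-data components: each draw is meant to answer "would this
   patient still look divergent if only these 50 proteins had been
   measured?", which requires a self-contained analysis. Degenerate draws
   (zero variance) are skipped and counted. A single seeded generator
   drives all draws; an `exhaustive` flag enumerates every m-subset instead
   (used for tiny validation problems).

The top-k analysis (default k = 50 by identification score, ties broken by
ascending accession) addresses the instability of low-scoring proteins,
which are quantified from few spectra.

### Properties relied on in tests

Scale invariance (global intensity rescaling leaves all distances
unchanged); m = n recovers the full-set distance exactly; the SVD route
agrees with a covariance-eigendecomposition oracle to 1e-8 on all small
matrices; exhaustive enumeration agrees with the brute-force subset
average.

## Synthetic intensity generator

The generator emulates a 14-patient × 139-protein label-free cohort in
which three patients (3, 4 and 12 under 1-based labels) carry a
blood-contamination signature:

- per-protein base abundance: log-normal, natural-log SD
  `abundance_sigma = 1.0` around a 1e6-unit center — roughly a 50-fold
  abundance span across the identified proteins, appropriate for the
  proteins actually identified in single-run protein-level data (the
  underlying fluid proteome spans far more, but the unidentified tail is
  invisible to this analysis);
- per-cell patient noise: multiplicative log-normal,
  `patient_sigma = 0.25` (~25% CV), typical label-free XIC
  reproducibility;
- contamination signature: 10% of proteins drawn **abundance-weighted**
  (probability proportional to base abundance) and multiplied by
  `outlier_effect = 4` in perturbed patients. Haemolysis adds abundant
  blood proteins — haemoglobin, albumin, transferrin — so the signature
  concentrates in the high-abundance stratum; a uniformly drawn signature
  would frequently consist of proteins too minor to perturb an
  unscaled-intensity PCA at all, which is not what blood contamination of
  a real sample looks like;
- missingness: cell goes missing with probability
  `missing_rate_base · (1 − q)²`, q the cell's abundance quantile in the
  dataset — low-abundance observations are the ones LC-MS fails to see;
  missing cells are emitted as explicit missing values, never zero;
- identification scores: log-normal around 50, correlated with mean
  protein abundance (more abundant proteins accumulate more spectra).

With these defaults the three perturbed patients occupy the top-3 mean
subsampled-distance ranks in ≥95 of 100 seeded replicates (the acceptance
suite measures this).

What the generator does **not** emulate: correlated protein co-regulation
(values are independent across proteins given abundance), peptide-level
rollup artifacts, batch/run-order drift, or heavy-tailed single-protein
outliers. Passing the recovery benchmark therefore shows the screen
detects a multiplicative multi-protein contamination signature against
realistic noise — not that it is robust to every failure mode of real
cohorts.

## Set-overlap evidence analysis

Identifier matching is exact string equality after canonicalization
(trailing `.<digits>` version suffix stripped, whitespace trimmed,
case-sensitive). No cross-database identifier mapping is attempted: the
analysis operates at accession level, and accession drift between database
releases is a known, accepted source of false "unique" proteins — the
targeted-MS follow-up exists precisely to catch those.

`ND` (tested, not detected) is count 0 with `tested = true`, distinct from
untested; a targeted result for a protein already present in a reference
database is rejected as inconsistent. Evidence flags:
`evidence_csf = in_csf_db ∨ targeted_peptides ≥ 1`,
`evidence_any = evidence_csf ∨ in_plasma_db`;
`n_any_evidence + n_unexplained = n_query` is an identity.

Annotation summaries are computed from a flat user-supplied
accession → category map per facet; a protein counts in every category it
carries, so percentages may sum past 100 (reported to one decimal).
Percentages are relative to the full accession-set size, with unannotated
proteins listed separately, so the two views can be reconciled.

The bundled evaluation fixture realizes 199 query proteins with query-side
regions 15 (neither database) / 89 (CSF only) / 3 (plasma only) / 92
(both) against reference sets of 2627 and 3017 accessions, with 11 of the
15 double-absent proteins detected by targeted MS. The CSF∩plasma overlap
*outside* the query set does not affect any query-side count and is fixed
arbitrarily at 1000 in the fixture.

## MRM method design

- **Digestion**: cleavage C-terminal of K/R, suppressed before proline
  (Keil rule; toggleable). Peptides carry 1-based parent coordinates; the
  0-missed-cleavage peptides tile the parent exactly.
- **Masses**: single constants table of monoisotopic residue masses
  (IUPAC/Unimod standard values, 5 decimals), water 18.01056 Da, proton
  1.00728 Da, carbamidomethyl +57.02146 Da applied per cysteine.
  y-ion = C-terminal fragment + water; b-ion = N-terminal fragment;
  `y_i + b_{n−i} = M + 2·proton` (singly charged) is enforced as a test
  identity.
- **Eligibility**: fully cleaved (0 missed cleavages, matching a targeted
  search configured without missed cleavages), length 7–25, no ambiguous
  residue, no methionine (oxidation-prone and therefore unreliable for
  quantification).
- **Ranking**: fewer missed cleavages, then length closest to 12 (the
  sweet spot for tryptic MRM peptides), then lexicographic — fully
  deterministic. Exactly `min_peptides` top-ranked peptides are selected
  per protein: the minimum is a per-protein budget, and taking more would
  inflate instrument time without improving protein-level confidence;
  proteins with fewer eligible peptides keep what they have and are
  reported as under-covered.
- **Transitions**: per peptide, the `transitions_per_peptide` highest-m/z
  singly-charged y-ions with fragment m/z above the (charge-2) precursor
  m/z, falling back to the highest available — fragments above the
  precursor avoid most low-mass interference.
- **Packing**: greedy, in protein/rank order, opening a new method when
  the next peptide's block would exceed capacity; a peptide's transitions
  are never split across methods, since a split peptide cannot be
  scheduled in one analysis.

Not modeled: retention-time scheduling, collision energies, interference
against a background proteome, dwell/cycle-time budgets.

## Identification acceptance rules

Two named rulesets reproduce common search-engine acceptance settings with
strict inequalities as configured there: a Spectrum-Mill-style set
(peptides: charge +2 score > 11 and %SPI > 60, charge +3 score > 13 and
%SPI > 70; proteins: score > 20; optional forward-reverse and rank-1−2
margins ≥ 2, relaxed to ≥ 1 for charge-2 spectra with score > 6 and
%SPI > 90 — records lacking the margin fields skip those predicates) and a
Scaffold-style set (probability > 0.95, proteins additionally ≥ 2
peptides). Records whose charge no rule covers are rejected by default
(configurable). Filtering is order-preserving and idempotent.

## Problem sizes in tests and the acceptance script

The acceptance suite runs the outlier-recovery benchmark at its full
stated size (100 replicates × 1000 subsampling iterations, ~15 s), the
digestion/mass property suite over 1000 random sequences, and the overlap
fixture at full published scale (5843 accessions); the whole suite
completes in well under a minute on one CPU, so nothing is scaled down.

## Known limitations

- The homogeneity screen flags divergence; it does not attribute it. A
  flagged patient may be contaminated, clinically different, or a
  technical failure.
- Per-axis SD standardization makes distances non-comparable across
  datasets with different patient counts.
- Set-level evidence is qualitative: presence in a reference database says
  nothing about comparable abundance.
- Transition lists are designed from sequence alone and must be validated
  on-instrument before quantitative use.
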