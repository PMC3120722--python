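# fluidprofiler

Tools for qualitative and semi-quantitative profiling of body-fluid
proteomes, built around three questions that arise when a poorly
characterized fluid (for example intracranial arachnoid cyst fluid) is
profiled by label-free LC-MS/MS across a patient cohort:

1. **Is the cohort homogeneous?** Given a proteins × patients XIC-intensity
   matrix, do any patients diverge systematically — e.g. because of blood
   contamination (haemolysis) or prior surgery — or is the protein profile
   shared?
2. **Which known fluid does it resemble?** Given the identified protein
   accessions and published reference proteomes (CSF, plasma), how much of
   the fluid's proteome is already explained, and what remains after
   following up the unexplained proteins with targeted MS?
3. **How do you follow up?** Design the in-silico part of a MIDAS-style
   targeted (MRM) assay: tryptic digestion, peptide/fragment masses, and
   transition lists packed into instrument methods.

A synthetic-data generator with known ground truth (which patients are
perturbed, the exact overlap structure, which proteins are detectable)
makes every stage testable without any external download.

## Methods in brief

**Homogeneity screen.** Intensities are total-sum normalized,
`x'(p,s) = x(p,s) · T(ref)/T(s)` where `T(s)` is patient *s*'s intensity
total. PCA treats patients as observations and mean-centered proteins as
variables; `explained_fraction_i = λ_i / Σλ`. Each patient's divergence is
the Euclidean norm of its first-two PC scores after dividing each axis by
its across-patient standard deviation — a distance from the sample mean in
SD units. Because single high-leverage proteins can fabricate such a
separation, the distance is stabilized by a subsampling scheme: draw *m* =
50 proteins at random, recompute PCA and distances on the sub-matrix,
repeat *B* = 1000 times, and average. Patients with a consistently large
mean subsampled distance are candidate outliers.

**Set-overlap evidence.** Accessions are canonicalized (version suffix
stripped) and partitioned into the seven Venn regions of
{query, CSF, plasma}. Proteins in neither reference database can be tested
by targeted MS; per protein, `evidence_csf = in_csf_db ∨ (peptides ≥ 1)`
and `evidence_any = evidence_csf ∨ in_plasma_db`. Summary counts report how
much of the query proteome is explained by each reference fluid.

**MRM design.** Trypsin cleaves C-terminal of K/R except before proline;
monoisotopic peptide mass = Σ residue masses + H₂O (+57.02146 Da per
carbamidomethylated cysteine); precursor m/z = (M + z·H⁺)/z. Per protein
the 3 best eligible fully-cleaved peptides (length 7–25, no Met) yield 3
high-m/z y-ion transitions each at precursor charge 2; transitions are
packed into methods of ≤ 100 without splitting a peptide.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from fluidprofiler import synthetic, homogeneity

cfg = synthetic.SyntheticConfig(seed=0)          # 139 proteins x 14 patients,
matrix, truth = synthetic.gen_intensity_dataset(cfg)  # patients 3/4/12 perturbed
report = homogeneity.homogeneity_report(matrix, k=50, m=50, B=1000, seed=0)
print(report.table.round(2))
```

```
     d_all  d_topk  d_subsampled_mean
P01   0.39    0.39               1.10
P02   0.64    0.64               0.81
P03   2.96    2.97               2.24
P04   1.99    1.98               1.92
...
P12   2.33    2.34               1.99
P13   0.62    0.61               0.56
P14   0.63    0.62               1.26
```

All three columns are distances from the sample mean in SD units: over all
proteins (`d_all`), over the 50 highest-scoring proteins (`d_topk`), and
averaged over 1000 random 50-protein subsamples (`d_subsampled_mean`). The
three simulated contaminated patients (P03, P04, P12 — `truth.perturbed_patients`)
hold the three largest mean subsampled distances; the stability of their
separation across random protein subsets is what distinguishes genuine
divergence from the influence of a few proteins.

The same analyses are available from the shell:

```bash
fluidprofiler simulate --patients 14 --proteins 139 --outliers 3,4,12 \
    --seed 7 --matrix-out m.tsv --truth-out truth.json
fluidprofiler homogeneity --matrix m.tsv --k 50 --m 50 --iterations 1000 \
    --seed 7 --report homogeneity.json
fluidprofiler compare-sets --ac ac.txt --csf csf.txt --plasma plasma.txt \
    --targeted targeted.tsv --report sets.json
fluidprofiler build-mrm --fasta targets.fasta --min-peptides 3 \
    --transitions 3 --capacity 100 --out transitions.csv
fluidprofiler reproduce --seed 42 --outdir out/   # all three, end to end
```

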