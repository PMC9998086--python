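# erna-scout

Discovery of enhancer-RNA (eRNA)-defined enhancers from cohort total
RNA-seq combined with ATAC-seq open-chromatin maps, with downstream
enhancer–gene linkage, disease-state classification and a prognostic
risk-score signature.

## The problem

Active enhancers produce short, unstable, typically *bidirectional*
transcripts (eRNAs). In a cohort comparison of Barrett's oesophagus (BO,
the pre-cancerous state) against oesophageal adenocarcinoma (OAC), eRNAs
measurable in total RNA-seq pinpoint enhancers that are gained or lost
during malignant progression — without any enhancer-specific assay.

The pipeline proceeds:

1. **Truncated genome.** From per-sample ATAC peak sets, build a union
   peak set (two peaks merge when they overlap or their centres lie within
   250 bp), then drop every peak touching a gene body, the 2 kb upstream
   of any TSS, or the 500 bp downstream of any TTS (strand-aware). What
   survives is intergenic open chromatin.
2. **Candidate eRNAs.** Count stranded RNA fragments per region (each
   fragment assigned by its midpoint), and keep regions with mean raw
   count ≥ 3 and mean FPM ≥ 1.5 across all samples. The directionality
   score `D = log10((plus+1)/(minus+1)) + 1` sits near 1 for balanced
   bidirectional transcription.
3. **Disease-specific eRNAs.** Median-of-ratios size factors, a
   negative-binomial Wald test per region (Var = μ + αμ², method-of-moments
   dispersion), Benjamini–Hochberg adjustment, and labels
   `|log2FC| > 0.5` at `padj < 0.05` (0.9 / 1.5 for cohort-specific
   mRNA modes).
4. **Target genes.** Nearest-gene assignment (signed TSS distance) and
   windowed best correlation: the gene with maximal Spearman ρ among those
   with a TSS within ±100 kb of the region centre. Gene-level consequences
   are summarised by the net enhancer change (#gained − #lost eRNAs within
   ±200 kb of the TSS, clamped to nine bins −4..+4) against the gene's
   expression shift (Kruskal–Wallis across bins).
5. **Classification.** Row z-scored eRNA expression, 1 − Pearson distance,
   average-linkage clustering cut at k = 2, scored as the minimum
   misclassification over cluster↔cohort assignments.
6. **Survival signature.** Univariate Cox screen (BH q < 0.1), top-6 |z|
   feature reduction, one multivariate Cox fit giving the risk score
   `Σ xᵢβᵢ`, a median split into low/high risk, and a Kaplan–Meier /
   log-rank comparison. Cox fits maximise the Breslow partial likelihood
   by Newton–Raphson.

Real patient data of this kind are access-controlled, so the package ships
a first-class synthetic-data generator (`erna_scout.simulate`) that plants
known eRNAs, eRNA-coupled target genes and survival effects in a toy
genome, giving every stage a measurable ground truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1     # writes results/sim/
python analysis/02_discover_ernas.py               # writes results/pipeline/
python analysis/03_evaluate_recovery.py            # scores vs planted truth
python analysis/04_survival_calibration.py         # n=500 survival check
```

At seed 1 this prints, in order: the study description
(`planted eRNAs: 40 (22 OAC-gained, 18 BO-lost) across 30 target genes`),
then the discovery funnel

```
pooled_peaks             16000
union_peaks              400
intergenic_regions       299
candidate_regions        234
A_specific               17
B_specific               22
```

— 16,000 per-sample peaks collapse to 400 union regions; all 100 decoy
peaks placed inside exclusion zones are removed (the one additional loss
is a boundary-jittered peak grazing a zone); 234 regions transcribe above
threshold; 39 are called cohort-specific. The evaluation table then shows
`recall 0.975`, `empirical_fdr 0.0` and `linkage_recovery 0.95` against
the planted truth, and the survival run recovers `beta_hat 0.7289` for a
true coefficient of 0.7, placing the planted gene in the top-6 signature
with log-rank p ≈ 7e-21 for the high/low risk split.

The same steps are available as a CLI (`erna-scout simulate|regions|
quantify|diff|link|cluster|survive|run`) for file-based use.

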