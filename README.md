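# acetylome

Downstream analysis of quantitative lysine-acetylome experiments, built for
the paired loss-of-function / gain-of-function deacetylase design: one
label-free run per condition (control shRNA, deacetylase shRNA, vector +
acetyltransferases, deacetylase overexpression + acetyltransferases), with
acetyl-peptide intensities quantified at the site level alongside a global
protein LFQ table.

Intended users are proteomics analysts who have site-level acetyl
quantification and want the full downstream chain — imputation,
normalization, target calling, error estimation, motif analysis and
enrichment — as reproducible, tested library code rather than spreadsheet
steps.

## The analysis

**Downshift imputation.** Missing label-free intensities are left-censored
(missing-not-at-random). With population mean μ and standard deviation σ of
all unimputed log2 intensities of a table, each eligible missing cell is
drawn from N(μ − 1.8σ, σ²) truncated to μ − 1.8σ ± 0.3σ. A comparison is
only retained when at most 1 of its 2 measurements was imputed, for the
acetyl pair and the protein pair independently; peptides of a protein never
quantified in an arm are excluded from that arm.

**Protein normalization.** For each site–arm pair the linear fold change is
normalized to the parent protein: `normalized = (acetyl_exp/acetyl_ctl) /
(LFQ_exp/LFQ_ctl)`, so protein-abundance shifts cancel and what remains is
stoichiometric acetylation change.

**Target classification.** At a strict 1.5-fold threshold, a peptide
(sequence + acetyl-site set) is a **direct** target when acetylation is up
under knockdown AND down under overexpression (anti-correlated with enzyme
level), **indirect** for the mirror pattern; protein-level calls use the
any-site rule per arm with gene-symbol consolidation.

**Sliding-threshold FPR.** Concordant decreases in both arms (−/−) are
biologically implausible and counted as false positives against all other
two-arm changes (+/−, −/+, +/+): FPR = fp/tp, swept over thresholds
1.0–1.5. Three scrambled pseudo-designs (like-pair nonsense ratios, and two
"difference of nonsense differences" second-order contrasts) re-run the
estimator with the treatment contrast destroyed, as negative controls.

**Motif analysis.** Greedy motif-x extraction on ±5 K-centered windows
against a proteome background (binomial p < 0.001, ≥ 12 occurrences,
position-specific background, deterministic tie-breaks), and a 20 × 21
signed −log10(p) Fisher-exact residue-enrichment heatmap on ±10 windows.

**Gene-set enrichment.** One-sided Fisher exact (hypergeometric upper tail)
of hit lists against GMT collections with the quantified-protein background
and Benjamini–Hochberg q-values.

**Synthetic experiments.** `generate_experiment(SimConfig(...))` produces a
proteome, both quant tables and ground-truth labels with planted effects,
protein-level shifts, and logistic MNAR dropout, so every stage is testable
end to end without any download.

## Worked example

```python
from acetylome import (DEFAULT_DESIGN, ImputationParams, SimConfig, call_dex,
                       classify_targets, compute_changes, generate_experiment,
                       impute, venn_summary)

experiment = generate_experiment(SimConfig(n_proteins=400, seed=11))
sites = impute(experiment.sites, ImputationParams(seed=1), DEFAULT_DESIGN)
proteins = impute(experiment.proteins, ImputationParams(seed=2), DEFAULT_DESIGN)
dex = call_dex(compute_changes(sites, proteins, DEFAULT_DESIGN), threshold=1.5)
summary = venn_summary(dex)
print(summary.direct_peptides, summary.direct_sites, summary.direct_proteins)
```

prints `31 31 31`: of 753 simulated acetyl sites, 31 peptides (each with one
site, on 31 proteins) pass the anti-correlation criterion in both arms —
the called direct deacetylase targets. The same dataset walked through every
stage, with the numbers each step prints and what they mean, lives in
`examples/01…06`; for instance `examples/04_fpr_sliding_threshold.py`
prints the real-design FPR (0.9% at 1.5-fold) against the scrambled
controls (49–576%), the internal evidence that the anti-correlation calls
are not artifacts.

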