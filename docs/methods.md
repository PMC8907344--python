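# Methods

## Study design and data model

The package models a 4-sample, 2-arm deacetylase perturbation: a knockdown
arm (enzyme-depleted vs. its paired control) and an overexpression arm
(enzyme-overexpressing vs. its paired control), one label-free run per
condition. Two tables drive everything: a site-level acetyl-peptide
intensity table (one row per peptide × acetyl-site set) and a global
protein LFQ table. Intensities are arbitrary linear LFQ units; site
coordinates are 1-based protein positions; an empty or zero cell means "not
quantified". All fold thresholds act on linear ratios; all distributional
operations (imputation, population statistics, noise) act on log2
intensities — a Gaussian downshift is only meaningful on a log scale, while
the 1.5-fold decision threshold is stated in linear units.

## Imputation

Missingness is treated as informative (left-censored): a missing value most
likely fell below the detection limit. With μ and σ the mean and SD of all
unimputed log2 values of the whole table (acetyl and protein tables kept
separate, samples pooled), each eligible missing cell receives an
independent draw from N(μ − d·σ, σ²) truncated to ± h·σ around the
downshifted mean, with defaults d = 1.8 and h = 0.3 — so all draws lie in
[μ − 2.1σ, μ − 1.5σ]. Draws use scipy's inverse-CDF truncated normal; the
defined contract is the distribution, not the random stream. A cell is
eligible only when the other measurement of its arm was observed; a fully
missing pair stays missing and the pair is excluded downstream
(`both_missing`). Degenerate populations (fewer than two observed values,
or σ = 0) are errors, not silent passes.

The pair rule is applied independently to the protein table: a site–arm
pair is retained iff ≤ 1 of 2 acetyl measurements was imputed, ≤ 1 of 2
parent-protein LFQ measurements was imputed, and the protein is quantified
at all; a protein with no usable LFQ pair in an arm excludes every one of
its peptides from that arm (`protein_unquantified`). Sites listing several
accessions are normalized against the first accession, with a warning.

## Normalization and classification

`normalized = raw / protein` holds exactly on every retained pair, making
normalization scale-invariant: rescaling one sample in both tables changes
nothing; rescaling only the acetyl table scales the affected arm's
normalized ratios by exactly that factor. Direction calls use strict
inequalities (ratio > t is "up", ratio < 1/t is "down", t = 1.5 by
default); a ratio exactly at the threshold is unchanged. Classification:
direct = up-in-knockdown AND down-in-overexpression on the identical
peptide; indirect = the mirror; protein level uses the any-site rule per
arm (a protein can be direct with the two conditions met by different
sites) after case-insensitive gene-symbol consolidation. Site-level counts
are global unique (accession, position) pairs and are reported alongside
peptide counts, because a site reached by distinct peptides is counted once
globally but once per peptide at the peptide level.

## Sliding-threshold FPR and scrambled nulls

Because the two arms move the enzyme in opposite directions, a site
decreasing in both comparisons (−/−) is implausible; the estimator counts
such items as false positives against all remaining two-arm changes with at
least one increase (+/−, −/+, +/+), FPR = fp/tp, over an ascending
threshold grid (default 1.0–1.5, step 0.01). FPR is NA — never 0 — when
tp = 0. Only items with ≤ 1 imputed measurement per comparison count. The
protein level qualifies via the any-site rule and is a false positive when
no qualifying site increases in either arm.

The scrambled schemes rebuild the changes table from pseudo-comparisons
with no usable treatment contrast:

* **scrambled1** — like-sample pairs: control_OE/control_KD and
  exp_OE/exp_KD.
* **scrambled2a** — the difference and the sum of the like-pair nonsense
  log-ratios (s7/s3 vs. s5/s1).
* **scrambled2b** — the difference and the sum of the cross-pair nonsense
  log-ratios (s3/s5 vs. s7/s1).

The second-order (difference/sum) construction is deliberate. A plain
cross-arm ratio such as exp_KD/control_OE is *not* a valid null: when the
two control backgrounds are statistically exchangeable it carries the full
treatment effect, and a direct target still produces the anti-correlated
(+, −) true-positive pattern, so its FPR simply tracks the real design; and
any shared background effect between the two HAT-boosted samples enters the
two cross ratios with opposite signs, again producing only true-positive
patterns. Differencing the nonsense ratios instead either zeroes the
treatment loading in one pseudo-comparison (scrambled1, scrambled2b) or
folds the anti-correlated effect into the concordant-decrease quadrant
(scrambled2a); in either case planted effects can only inflate, never
deflate, the scrambled FPR. Both scrambled-2 variants are offered because
the second-order construction is ambiguous about which nonsense pairs it
differences; neither is asserted as canonical. For composite contrasts the
≤ 1-imputed rule is applied over the contrast's samples, and a value that
could not be imputed (whole real-design pair missing) excludes the item.

## Motif extraction and residue heatmap

Extraction follows greedy motif-x on ±5 K-centered windows: among all
(position ≠ 0, residue) candidates with a one-sided binomial p below the
threshold (default 0.001) and at least `min_occurrences` (default 12)
foreground matches, fix the candidate with the smallest p — ties broken by
larger count, then leftmost position, then alphabetical residue — restrict
foreground and background to matching windows, and recurse; when no
candidate qualifies the fixed set is emitted as a motif, its windows are
removed from the foreground, and the search restarts. Motifs are therefore
mutually exclusive on the foreground. The background is position-specific
(all K-centered windows of the supplied proteome) because the recursion
conditions on prior fixed positions; padding never counts as a residue and
per-position totals are used throughout. The occurrence floor is a
*minimum*: a maximum would make the greedy procedure vacuous.

Null calibration, measured analytically and by simulation: with a
200-window null foreground the summed attained levels of the ~200 candidate
tests at p < 0.001 give ≈ 0.09 expected false fixes per extraction, i.e.
roughly one seed in eleven produces a spurious motif; at the stringent
1e-6 threshold spurious motifs essentially vanish. This is the usual
multiplicity cost of running motif-x at a permissive per-candidate
threshold and is asserted, at its true rate, in the test suite.

The heatmap is computed on ±10 windows: for each residue × position, a
two-sided Fisher exact test of foreground vs. background per-position
counts, signed by over-/under-use, reported as sign × −log10(p), with the
always-K center column masked. Windows are stored at ±15 and trimmed to ±5
for extraction and ±10 for the heatmap.

## Gene-set enrichment

One-sided hypergeometric upper-tail p per term, background = all quantified
proteins (configurable), set members intersected with the background before
testing, terms with zero overlap dropped, BH q-values across tested terms.
The test depends only on (k, n, K, N), so the set membership of other
background genes is irrelevant. No ontology-graph pruning is attempted.

## The synthetic generator

`SimConfig` defaults emulate the study scale: 1414 proteins, ~2 acetyl
sites each (≈ 2850 sites), log2 intensity mean 25 / SD 2 (a typical
MaxQuant LFQ scale), 5% direct and 15% indirect sites, |log2 effect| = 1
(2-fold), protein-level per-sample shifts with SD 0.25 that enter both
tables (so normalization must cancel them), and logistic MNAR dropout with
midpoint two SDs below the intensity mean and slope 1 per log2 unit
(slope 0 disables dropout). One replicate per condition, exactly as the
design assumes; the generator refuses n > 1 rather than averaging.

`noise_sd` (default 0.2) is the SD of the log2 noise of a *two-sample
ratio* — the quantity every threshold acts on; each measurement receives
independent N(0, noise_sd/√2). The protein table has its own
`protein_noise_sd` (default 0: protein LFQ, averaged over many peptides, is
treated as precise relative to single-peptide acetyl signals; its
between-sample variation is `protein_change_sd`, which normalization
cancels).

Protein sequences are i.i.d. draws from human amino-acid frequencies with
K forced at planted site positions. The generator therefore reproduces the
distributional assumptions the pipeline relies on — log-normal intensities,
left-censored dropout, anti-correlated planted effects, protein-abundance
confounding — but none of the structure of real acetylomes it does not
need: no homology, no tryptic-digest peptide dependency, no shared peptides
across proteins, no correlated missingness between acetyl and protein
tables, no batch structure beyond the per-sample protein shifts. Passing
tests demonstrate the *algorithms* are correct under the stated model, not
that the model captures every pathology of real data.

## Numerical and design choices

* Simulation sizes: classification recovery uses the stated 5,000 sites
  with sensitivity/FDP averaged over five generator seeds, because a single
  realization has ~500 direct sites and a Monte Carlo SE (~0.009)
  comparable to the margin being asserted; the scrambled-dominance check
  uses ~20,000 sites so the scrambled schemes' tail counts at 1.5-fold are
  stably nonzero.
* Imputation draws, generator output and the whole pipeline are pure
  functions of their seeds; identical seeds give bit-identical tables.
* Exact-threshold ratios are "unchanged" (strict inequalities), FPR with
  tp = 0 is NA, empty inputs yield empty outputs or explicit errors as
  documented per function — never silent zeros.
* Fisher two-sided p-values use scipy's minimum-likelihood convention; the
  tests verify them against exact-fraction hypergeometric enumeration.
* Known limitations: no razor-peptide/protein-grouping logic, no
  variance-stabilizing normalization or batch correction, no moderated
  statistics (calls are pure fold thresholds, as the design intends), no
  ontology pruning, and the scrambled-2 construction is offered in two
  labeled interpretations rather than one canonical form.
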