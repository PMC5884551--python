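# Methods

## Scope and model

`psgscan` implements a branch-site scan for positive selection together
with a two-species aging-expression analysis, on synthetic data with known
ground truth. The codon model is the Goldman–Yang form: substitutions
change one nucleotide at a time with rate `π_target · κ^[ts] · ω^[nonsyn]`,
and the branch-site Model A mixture assigns each site to one of four
classes (0, 1, 2a, 2b) whose ω differs between the single foreground branch
and all background branches (see the README table). Both nested models are
fit by maximum likelihood; the likelihood-ratio statistic is referred to
χ²₁ by default (the conservative convention), with the ½δ₀+½χ²₁ boundary
mixture available via `lrt(..., null_distribution="mixture")`.

Assumptions worth stating explicitly: no recombination within a gene,
site-independent evolution, a single foreground branch per test, stationary
and reversible substitution with frequencies shared across branches, and no
indel process (alignment inference is not a tested stage).

## Likelihood and optimization

Likelihoods use the pruning algorithm over 61 sense-codon states with
alignment-column pattern compression, per-node rescaling against underflow,
and a batched pass over the four site classes. Transition matrices come
from the eigendecomposition of the π-symmetrized generator; the public
`transition_probabilities` uses scipy's `expm` and the test suite checks the
two paths against each other and against an exhaustive enumeration over all
internal-node state assignments (agreement ≤ 1e-8 on 4-taxon alignments).

Free parameters are κ, ω0, ω2 (alternative only), the mixture weights
(p0, p1) via a stick-breaking transform, and one per-gene scale factor `s`
multiplying all branch lengths — per-branch re-estimation is deliberately
out of scope; the input tree fixes relative lengths. Optimization is
bounded L-BFGS-B on log/logit-transformed parameters with numerically
estimated gradients, convergence when lnL improves by less than ~1e-6, and
a function-evaluation cap (default 600 for single fits; the scan harnesses
use 200–400, which on the simulated gene sizes changes fitted lnL by less
than the LRT's numerical tolerance).

Because the null and alternative surfaces are multimodal, the pair is fit
by a cross-initialized ladder (`fit_nested`): null from a fixed default
start, alternative from the null MLE plus a high-ω2 start with freed class-2
mass, then each model is refit from the other's MLE until neither improves.
This prevents the statistic from reflecting one model finding a basin the
other missed; the statistic is finally clamped at zero. Control reruns
(below) add fresh random starting points.

## Equilibrium frequencies

`f3x4_frequencies` implements the standard position-frequency product
estimator. For *fitting*, the default is a lightly smoothed empirical
codon-usage estimator (`empirical_codon_frequencies`, pseudocount 0.5), and
the multi-gene scan pools codon usage across the whole gene set
(`pooled_codon_frequencies`) — the analog of using genome-wide codon usage.
The reason is robustness: on 100-codon alignments, per-gene frequency
estimates are noisy enough that the foreground-specific ω2 parameter can
absorb the composition misfit and inflate the LRT's type-I error severalfold;
with pooled empirical usage the measured null rejection rate at α=0.05 is
~2% (conservative, as expected for this test). F3x4 fitting remains
available (`fit_model(freq_estimator="f3x4")`).

## Multi-branch screening

Per branch: LRT per gene → Benjamini–Hochberg within the branch (per-branch
FDR matches the per-branch reporting convention; a joint-FDR variant would
only require concatenating records) → candidates at q < 0.1 (strict) → two
control reruns per candidate from fresh random starts. A rerun's p-value is
evaluated on the best null and best alternative log-likelihoods seen across
the main run and that rerun, so approval is withdrawn exactly when a rerun
finds a *better* optimum that erases the signal — the convergence-artifact
signature this guard exists for — and never because a random restart merely
underconverged. Gene eligibility per branch requires the foreground clade's
species plus at least one sister-clade species in the alignment, so detected
selection cannot predate the tested branch. Bias checks compare PSGs with
the other tested genes by two-sided Mann–Whitney tests on taxon coverage,
codon length, mean GC, and cross-species GC spread; all-tied features report
p = 1.

## Differential expression and the pleiotropy tests

The DE stage is a minimal negative-binomial Wald test: median-of-ratios
size factors; per-gene method-of-moments dispersion floored at 1e-8 and
shrunk halfway toward a fitted `a0 + a1/μ` mean-dispersion trend; a
delta-method Wald z on the log2 ratio of group means of normalized counts
with a normal reference. Measured on the null simulation (no regulated
genes, default cohort sizes), the empirical type-I rate at p < 0.05 is
~0.06. Externally produced LFC/q tables can be substituted — all downstream
operations consume plain `DeRecord` lists.

Genes regulated (q ≤ 0.1) in both species are placed in sign quadrants;
genes regulated in only one species are excluded (the analog of insufficient
expression in one species), as are exact-zero LFCs among the regulated
(direction-less; measure-zero in practice). Quadrant-I PSG excess uses the
one-sided Fisher exact test of {PSG, other} × {I, II+III+IV}. The
directionality test computes, per species, a one-sided Fisher p for PSG
preference toward the longevity-consistent direction (down in the
long-lived species, up in the short-lived one) among that species' regulated
genes, and combines the two with the Lancaster procedure at equal weights 2,
i.e. Fisher's method; the construction of the Lancaster inputs is this
package's documented choice and no equivalence with any published combined
p-value is claimed. Because the Fisher components are discrete, the
combined directional p is strictly conservative under random PSG labels
(measured mean p ≈ 0.62, ~2.5% of null p-values below 0.05); calibration is
therefore validated one-sidedly — no excess of small p-values — rather than
by exact uniformity, which no discrete exact test can attain. Enrichment is flat-table hypergeometric (no ontology
graph), the fold-change set test is a per-direction Welch t of member vs
non-member LFCs, and category unions/overlap tests reuse the same
hypergeometric tail.

## Synthetic-data generator: what it emulates, and what not

* **Trees** — random join order, branch lengths Uniform(0.5, 1.5)·depth
  with depth defaulting to 0.05 substitutions/codon: the shallow scale of a
  rodent family tree. Real topological structure (clade imbalance,
  rate variation among lineages) is not emulated.
* **Codon alignments** — exact sampling from the per-branch transition
  matrices of the Model A process, root drawn from π (reversibility makes
  root placement irrelevant). Default π is the product law of fixed
  mammalian-like position-specific nucleotide frequencies (GC3-rich third
  position). No indels, no alignment error, no stop-codon states: tests on
  these data validate the selection machinery, not robustness to alignment
  artifacts.
* **Counts** — NB(μ, α) via gamma–Poisson with a single shared dispersion
  (default α = 0.05, a conventional bulk-RNA-seq value; the real study's
  dispersion is unknown), log-normal baseline means, cohort sizes 6/3
  (long-lived species young/old) and 4/5 (short-lived species) matching the
  liver RNA-seq design. Regulated genes get |LFC| = 0.5 + |N(0,1)|; planted
  PSGs are regulated in both species and fall in quadrant I with probability
  `q1_prob` (default 0.8). Library-size variation, batch effects and
  mean-dependent dispersion are not emulated.
* **CDS catalogs** — per-gene ancestral cores (60–120 codons) mutated
  per-site at the stated divergence, never creating internal stops;
  isoforms share the core and append exon-like blocks. Paralogy is not
  generated by default (tests construct paralogs explicitly).

## Validation experiments and problem sizes

`psgscan/experiments.py` holds the shared harnesses; the suite and
`scripts/acceptance.py` run them at desk-scale sizes chosen to keep total
runtime in the tens of minutes on one CPU: null LRT calibration at 200
replicates (4 taxa, 100 codons), ω2 recovery at 20 replicates (6 taxa, 500
codons, ω2 = 8, class-2 mass 0.2), realized-FDR scans at 3 replicates of
30 genes (300 codons) with 10% planted signal, directionality power and
null calibration at 50 replicates each, RBH recovery on 50-gene catalogs.
Larger sizes tighten the Monte-Carlo error but do not change the
procedures. The branch-site test has modest per-gene power on short
terminal branches at 4 taxa — a documented property of the test — so the
FDR experiment's planted recall is reported alongside the (always
controlled) false-discovery proportion, while the dedicated power
experiment uses the more informative 6-taxon, 500-codon setting.

## Numerical choices and edge cases

Gaps and N-containing codons are missing data (unit partial likelihood);
an all-gap column contributes zero log-likelihood. Position frequencies in
F3x4 are floored at 1e-6; pooled F61 uses pseudocount 0.5 per codon. The
LRT statistic is clamped at zero; p-values are capped at 1. Ties in
reciprocal best hits and isoform selection break by (score, then longest
CDS, then lexicographic id); progressive alignment joins sequences by
descending anchor similarity; alignment columns with >50% gaps are removed
and species retaining <50% non-gap codons are dropped (these two filter
values are this package's own, configurable per call). Degenerate Fisher
margins return p = 1 with a warning; a combined p of exactly 0 is clamped
to the smallest positive float with a warning.

## Known limitations

The test's reference distribution is asymptotic and conservative at these
alignment lengths; fitted ω0 and the mixture weights are weakly identified
on 4-taxon, 100-codon genes (ω̂0 frequently hits a boundary under the null
without affecting calibration). Bayes empirical Bayes site identification,
site-model tests, multiple foreground branches, and per-branch length
re-estimation are out of scope. The expression stage models two conditions
only. None of the headline counts of the motivating study design
(genome-scale PSG counts on real 17-species data) are reproducible at this
scale, and the package does not attempt them.
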