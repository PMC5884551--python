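# psgscan

A desk-scale, fully tested pipeline for detecting **positively selected genes
(PSGs)** on longevity-associated phylogenetic branches and testing whether
those genes behave as the **antagonistic pleiotropy** theory of aging
predicts — down-regulated with age in a long-lived species and up-regulated
in a short-lived one.

The package targets the analysis style of comparative rodent aging studies
(African mole-rats and relatives): per-species CDS catalogs are reduced to
one representative ortholog per gene via reciprocal best hits against an
anchor species, per-gene codon alignments are scanned with the branch-site
test of positive selection on designated foreground branches, candidates are
FDR-controlled and guarded by convergence control reruns, and the surviving
PSG set is intersected with young-vs-old liver expression in two species.
A synthetic-data module generates every input with known ground truth, so
each stage's statistical behaviour (type-I error, power, realized FDR) is
verifiable end to end.

## The model at the core

Codon substitution follows a Goldman–Yang generator over the 61 sense
codons: `q_ij = π_j · κ^[transition] · ω^[nonsynonymous]` for single-
nucleotide changes, zero otherwise. The branch-site "Model A" mixture puts
each site in one of four classes:

| class | proportion | background ω | foreground ω |
|-------|------------|--------------|--------------|
| 0     | p0         | ω0 ∈ (0,1)   | ω0           |
| 1     | p1         | 1            | 1            |
| 2a    | (1−p0−p1)·p0/(p0+p1) | ω0 | ω2 ≥ 1 |
| 2b    | (1−p0−p1)·p1/(p0+p1) | 1  | ω2 ≥ 1 |

The null fixes ω2 = 1; the statistic 2·(lnL_alt − lnL_null), clamped at
zero, is referred to χ²₁ (conservative). Per-gene q-values come from
Benjamini–Hochberg within each branch; candidates (q < 0.1) are refit twice
from fresh random starts and approved only if the rerun stays inside the
branch's significance region. Genes regulated (q ≤ 0.1) at old vs young age
in *both* species are placed in fold-change quadrants; quadrant I
(LFC_A < 0, LFC_B > 0) is tested for PSG excess with a one-sided Fisher
exact test, and the two per-species directional Fisher p-values are
combined with the Lancaster procedure (equal weights 2 — Fisher's method).

## Worked example

```python
from psgscan.io import RunConfig
from psgscan.pipeline import run_pipeline

config = RunConfig(seed=1, outdir="scratch/demo", n_scan_genes=10,
                   n_taxa=6, n_codons=300, n_expression_genes=1200,
                   selected_fraction=0.3)
summary = run_pipeline(config)
print(summary["scan"])
print(summary["expression"]["directionality"])
```

On this configuration the run printed:

```
{'branches': ['sp1'], 'tested': 10, 'candidates': 3, 'psgs_union': 3,
 'true_positives': 3, 'multi_branch_genes': 0}
{'p_down_in_a': 0.2707..., 'p_up_in_b': 0.1061..., 'p_combined': 0.1307...}
```

Three of the ten simulated genes were planted with ω2 = 8 on the foreground
branch; the scan recovered all three with no false discoveries. The
expression stage placed two of them in quadrant I (one-sided Fisher
p = 0.053) — with only three PSGs the directional Lancaster combination is
deliberately underpowered here (p = 0.13); the validation harness
(`psgscan.experiments.directionality_power`), which plants 60 PSGs at the
default quadrant-I probability 0.8, detects the direction in well over 90%
of replicates. The same pipeline is available from the shell
(`psgscan all --seed 1 --outdir scratch/demo`), with subcommands for each
stage.

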