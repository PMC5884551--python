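"""Synthetic inputs with ground truth for every pipeline stage.

Four generators:

* random rodent-like phylogenies with one taggable foreground branch,
* codon alignments evolved under the branch-site Model A mixture (exact
  sampling from per-branch transition matrices; no indels),
* young-vs-old negative-binomial count matrices for two species with a
  planted excess of positively selected genes that are down-regulated with
  age in the long-lived species and up-regulated in the short-lived one,
* multi-isoform CDS catalogs with known cross-species orthology.

All randomness flows through an explicit integer seed; identical arguments
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from psgscan import codons
from psgscan.errors import InvalidArgumentError
from psgscan.selection import (
    BranchSiteParams,
    CodonAlignment,
    scaled_generators,
    _CLASS_OMEGAS,
    _SpectralGenerator,
    CLASS_NAMES,
)
from psgscan.trees import Phylogeny


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated dataset.

    Only the fields relevant to the generator that produced it are filled.
    """

    site_classes: list[str] | None = None  # per-site Model A class: 0/1/2a/2b
    gene_selected: dict[str, bool] = field(default_factory=dict)
    lfc_a: dict[str, float] = field(default_factory=dict)
    lfc_b: dict[str, float] = field(default_factory=dict)
    ortholog_pairs: set[tuple[str, str, str, str]] = field(default_factory=set)
    # (species1, gene1, species2, gene2) with species1 < species2

    def __post_init__(self):
        if self.site_classes is not None:
            bad = set(self.site_classes) - set(CLASS_NAMES)
            if bad:
                raise InvalidArgumentError(f"unknown site classes {bad}")


@dataclass
class CountSimSpec:
    """Study design of the two-species aging count simulation.

    Cohort defaults follow the liver RNA-seq design: species A (long-lived)
    with 6 young / 3 old animals, species B (short-lived) with 4 young / 5
    old.  ``dispersion`` is the NB alpha in Var = mu + alpha * mu^2, shared
    across genes by default.  ``q1_prob`` is the probability that a planted
    PSG shows the antagonistic-pleiotropy pattern (down in A, up in B).
    """

    n_genes: int = 2000
    samples_a: tuple[int, int] = (6, 3)  # (young, old)
    samples_b: tuple[int, int] = (4, 5)
    dispersion: float = 0.05
    regulated_fraction: float = 0.2
    effect_sd: float = 1.0
    min_effect: float = 0.5
    psg_count: int = 100
    q1_prob: float = 0.8
    mean_log_mu: float = 6.0
    sd_log_mu: float = 1.2
    seed: int = 0
    #: explicit PSG gene indices; overrides the random psg_count draw
    psg_indices: tuple[int, ...] | None = None

    def __post_init__(self):
        for p in (self.regulated_fraction, self.q1_prob):
            if not 0 <= p <= 1:
                raise InvalidArgumentError("probabilities must lie in [0, 1]")
        for n in (*self.samples_a, *self.samples_b):
            if n < 2:
                raise InvalidArgumentError("need >= 2 samples per age group")
        if self.dispersion <= 0:
            raise InvalidArgumentError("dispersion must be positive")
        if self.n_genes < 1 or self.psg_count < 0 or self.psg_count > self.n_genes:
            raise InvalidArgumentError("invalid gene counts")
        if self.psg_indices is not None and any(
            not 0 <= i < self.n_genes for i in self.psg_indices
        ):
            raise InvalidArgumentError("psg_indices out of range")


# ---------------------------------------------------------------------------


def simulate_tree(n_taxa: int, depth: float = 0.05, seed: int = 0) -> Phylogeny:
    """Random rooted binary tree by successive pair joining.

    Branch lengths are Uniform(0.5, 1.5) * depth, mimicking a shallow
    rodent-scale tree (a few hundredths of a substitution per site).
    """
    if n_taxa < 2:
        raise InvalidArgumentError("need at least two taxa")
    if depth <= 0:
        raise InvalidArgumentError("depth must be positive")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=int)
    lengths = np.zeros(n_nodes)
    labels = [""] * n_nodes
    width = len(str(n_taxa))
    for i in range(n_taxa):
        labels[i] = f"sp{i + 1:0{width}d}"
    active = list(range(n_taxa))
    nxt = n_taxa
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        lengths[a] = rng.uniform(0.5, 1.5) * depth
        lengths[b] = rng.uniform(0.5, 1.5) * depth
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    # children indices are always smaller than parents: 0..n_nodes-1 is a postorder
    return Phylogeny(
        parent=parent,
        lengths=lengths,
        labels=labels,
        postorder=np.arange(n_nodes),
        foreground=None,
    )


def simulate_codon_alignment(
    tree: Phylogeny,
    params: BranchSiteParams,
    n_codons: int,
    foreground: int | str | None = None,
    seed: int = 0,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment under the branch-site Model A mixture.

    Each site draws a class from (p0, p1, p2a, p2b); the root codon comes
    from pi and every branch applies the exact transition matrix of the
    class's (background or foreground) generator — stop codons can never
    arise because the state space is the 61 sense codons.
    """
    if n_codons < 1:
        raise InvalidArgumentError("n_codons must be >= 1")
    if foreground is not None:
        tree = tree.with_foreground(foreground)
    fg = tree.foreground
    rng = np.random.default_rng(seed)

    props = params.proportions
    classes = rng.choice(4, size=n_codons, p=props / props.sum())
    gens = scaled_generators(params)
    spectral = [_SpectralGenerator(Q, params.pi) for Q in gens]

    root = tree.root
    states = np.empty((tree.n_nodes, n_codons), dtype=np.int64)
    states[root] = rng.choice(codons.N_CODONS, size=n_codons, p=params.pi)
    # preorder: reversed postorder visits parents before children
    for node in tree.postorder[::-1]:
        if node == root:
            continue
        t = tree.lengths[node] * params.scale
        for c, (bg_idx, fg_idx) in enumerate(_CLASS_OMEGAS):
            sites = np.flatnonzero(classes == c)
            if sites.size == 0:
                continue
            regime = fg_idx if (fg is not None and node == fg) else bg_idx
            if t == 0:
                states[node, sites] = states[tree.parent[node], sites]
                continue
            P = spectral[regime].expm(t)
            cum = np.cumsum(P, axis=1)
            u = rng.random(sites.size)
            rows = cum[states[tree.parent[node], sites]]
            states[node, sites] = (rows < u[:, None]).sum(axis=1)

    leaves = tree.leaves
    seqs = [
        "".join(codons.CODONS[s] for s in states[leaf]) for leaf in leaves
    ]
    aln = CodonAlignment(species=[tree.labels[leaf] for leaf in leaves], seqs=seqs)
    truth = SimulationTruth(site_classes=[CLASS_NAMES[c] for c in classes])
    return aln, truth


# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, alpha) with Var = mu + alpha mu^2, via the gamma-Poisson mixture."""
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(spec: CountSimSpec):
    """Two-species young-vs-old count matrices with planted directional PSGs.

    Returns (counts_a, counts_b, truth).  Count matrices are
    :class:`psgscan.expression.CountMatrix` instances; truth records every
    gene's true log2 fold-change per species and its PSG status.
    """
    from psgscan.expression import CountMatrix  # deferred: avoids an import cycle

    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]

    base_mu = np.exp(rng.normal(spec.mean_log_mu, spec.sd_log_mu, size=spec.n_genes))
    regulated = rng.random(spec.n_genes) < spec.regulated_fraction
    if spec.psg_indices is not None:
        psg_idx = np.asarray(sorted(spec.psg_indices), dtype=int)
    else:
        psg_idx = rng.choice(spec.n_genes, size=spec.psg_count, replace=False)
    is_psg = np.zeros(spec.n_genes, dtype=bool)
    is_psg[psg_idx] = True

    def draw_effect(n):
        mag = spec.min_effect + np.abs(rng.normal(0.0, spec.effect_sd, size=n))
        return mag

    lfc_a = np.zeros(spec.n_genes)
    lfc_b = np.zeros(spec.n_genes)
    reg = np.flatnonzero(regulated)
    lfc_a[reg] = draw_effect(reg.size) * rng.choice([-1.0, 1.0], size=reg.size)
    lfc_b[reg] = draw_effect(reg.size) * rng.choice([-1.0, 1.0], size=reg.size)
    # planted PSGs are regulated in both species; with probability q1_prob the
    # pattern is antagonistic-pleiotropy quadrant I (down in A, up in B)
    for g in psg_idx:
        forced = rng.random() < spec.q1_prob
        mag_a, mag_b = draw_effect(2)
        sign_a = -1.0 if forced else rng.choice([-1.0, 1.0])
        sign_b = 1.0 if forced else rng.choice([-1.0, 1.0])
        lfc_a[g] = sign_a * mag_a
        lfc_b[g] = sign_b * mag_b

    def species_matrix(species, n_young, n_old, lfc):
        mu_young = np.tile(base_mu[:, None], (1, n_young))
        mu_old = np.tile((base_mu * 2.0 ** lfc)[:, None], (1, n_old))
        counts = np.concatenate(
            [
                _nb_draw(rng, mu_young, spec.dispersion),
                _nb_draw(rng, mu_old, spec.dispersion),
            ],
            axis=1,
        )
        samples = [f"{species}_young_{i + 1}" for i in range(n_young)] + [
            f"{species}_old_{i + 1}" for i in range(n_old)
        ]
        condition = ["young"] * n_young + ["old"] * n_old
        return CountMatrix(
            genes=list(genes),
            samples=samples,
            counts=counts,
            condition=condition,
            species=species,
        )

    counts_a = species_matrix("speciesA", *spec.samples_a, lfc_a)
    counts_b = species_matrix("speciesB", *spec.samples_b, lfc_b)
    truth = SimulationTruth(
        gene_selected={g: bool(s) for g, s in zip(genes, is_psg)},
        lfc_a={g: float(x) for g, x in zip(genes, lfc_a)},
        lfc_b={g: float(x) for g, x in zip(genes, lfc_b)},
    )
    return counts_a, counts_b, truth


# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    """ATG + random sense codons + stop, as a codon list."""
    body = [codons.CODONS[i] for i in rng.choice(codons.N_CODONS, size=n_codons)]
    stop = sorted(codons.STOP_CODONS)[rng.choice(3)]
    return ["ATG"] + body + [stop]


def _mutate_codons(
    rng: np.random.Generator, cds: list[str], divergence: float
) -> list[str]:
    """Per-nucleotide substitutions at the given rate, never creating stops."""
    out = [cds[0]]  # keep ATG
    for cod in cds[1:-1]:
        cod = list(cod)
        for pos in range(3):
            if rng.random() < divergence:
                alt = [n for n in codons.NUCLEOTIDES if n != cod[pos]]
                new = list(cod)
                new[pos] = alt[rng.choice(3)]
                if "".join(new) not in codons.STOP_CODONS:
                    cod = new
        out.append("".join(cod))
    out.append(cds[-1])
    return out


def simulate_cds_catalog(
    n_genes: int,
    n_species: int,
    isoforms_per_gene: int = 1,
    divergence: float = 0.05,
    seed: int = 0,
    core_codons: tuple[int, int] = (60, 120),
):
    """Multi-isoform CDS catalogs for several species with known orthology.

    Each gene has an ancestral core CDS; species orthologs are derived by
    per-site substitution at ``divergence``; extra isoforms append an
    exon-like codon block before the stop so all isoforms of a gene share
    the core.  Returns ({species: [CdsRecord]}, truth) with every true
    cross-species ortholog pair recorded.
    """
    from psgscan.orthology import CdsRecord  # deferred: avoids an import cycle

    if min(n_genes, n_species, isoforms_per_gene) < 1:
        raise InvalidArgumentError("all arguments must be >= 1")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]

    catalogs: dict[str, list[CdsRecord]] = {sp: [] for sp in species}
    truth = SimulationTruth()
    for gene in genes:
        core = _random_cds(rng, int(rng.integers(*core_codons)))
        extras = [
            [codons.CODONS[i] for i in rng.choice(codons.N_CODONS, size=12)]
            for _ in range(isoforms_per_gene - 1)
        ]
        for sp in species:
            sp_core = _mutate_codons(rng, core, divergence)
            for k in range(isoforms_per_gene):
                cds = list(sp_core)
                if k > 0:
                    cds = cds[:-1] + extras[k - 1] + [cds[-1]]
                catalogs[sp].append(
                    CdsRecord(
                        gene=gene,
                        species=sp,
                        isoform=f"iso{k + 1}",
                        seq="".join(cds),
                        source="transcriptome",
                    )
                )
        for i in range(n_species):
            for j in range(i + 1, n_species):
                truth.ortholog_pairs.add((species[i], gene, species[j], gene))
    return catalogs, truth
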