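"""Branch-site test of positive selection on a designated foreground branch.

The model is the standard branch-site "Model A" mixture over four site
classes.  Sites in class 0 evolve with 0 < omega0 < 1 everywhere, class 1
with omega1 = 1 everywhere; classes 2a and 2b inherit the background
behaviour of classes 0 and 1 but switch to omega2 >= 1 on the single
foreground branch.  The null hypothesis fixes omega2 = 1; twice the
log-likelihood difference is referred to a chi-square distribution with one
degree of freedom (optionally the 1/2 point-mass + 1/2 chi-square mixture).

Substitution follows a Goldman-Yang style codon generator: single-nucleotide
changes only, transition/transversion ratio kappa, target-codon frequency
pi_j, and omega multiplying nonsynonymous rates.  Generators for the two
omega regimes share one scale factor so that the mixture-average rate is one
substitution per codon per unit branch length; a per-gene tree scale factor
is estimated instead of per-branch lengths.

Likelihoods use the pruning algorithm over the 61 sense-codon states with
per-node rescaling; gaps and ambiguous codons are missing data (partial
likelihood one over all states).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize, stats
from scipy.special import logsumexp

from psgscan import codons
from psgscan.errors import (
    FitError,
    InvalidArgumentError,
    MissingForegroundError,
    SpeciesMismatchError,
)
from psgscan.trees import Phylogeny

# ---------------------------------------------------------------------------
# containers


@dataclass
class CodonAlignment:
    """In-frame codon alignment: one nucleotide string per species.

    Sequences have equal length, a multiple of three; '---' is a gap codon
    and codons containing N are treated as missing data.  Stop codons are
    rejected.
    """

    species: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.species) != len(self.seqs):
            raise InvalidArgumentError("species/sequence count mismatch")
        if not self.seqs:
            raise InvalidArgumentError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise InvalidArgumentError("unequal sequence lengths")
        (length,) = lengths
        if length % 3:
            raise InvalidArgumentError("alignment length not a multiple of 3")
        self.seqs = [s.upper() for s in self.seqs]
        for sp, s in zip(self.species, self.seqs):
            for k in range(0, length, 3):
                if s[k : k + 3] in codons.STOP_CODONS:
                    raise InvalidArgumentError(f"stop codon in {sp} at codon {k // 3}")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    @property
    def n_species(self) -> int:
        return len(self.species)

    def codon(self, row: int, site: int) -> str:
        return self.seqs[row][3 * site : 3 * site + 3]

    def state_matrix(self) -> np.ndarray:
        """(n_species, n_codons) sense-codon indices; -1 for gap/ambiguous."""
        out = np.full((self.n_species, self.n_codons), -1, dtype=np.int64)
        for i, s in enumerate(self.seqs):
            for j in range(self.n_codons):
                out[i, j] = codons.CODON_INDEX.get(s[3 * j : 3 * j + 3], -1)
        return out


@dataclass
class BranchSiteParams:
    """Model A parameter set.

    kappa   transition/transversion rate ratio (> 0)
    omega0  purifying dN/dS of class 0, in (0, 1)
    omega2  foreground dN/dS of classes 2a/2b, >= 1 (fixed to 1 under the null)
    p0, p1  mixture weights of classes 0 and 1; p2a/p2b are derived by
            splitting 1 - p0 - p1 proportionally to p0 : p1
    pi      equilibrium frequencies over the 61 sense codons
    scale   per-gene multiplier applied to all branch lengths
    """

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    pi: np.ndarray = field(default_factory=lambda: DEFAULT_PI.copy())
    scale: float = 1.0

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise InvalidArgumentError("kappa must be positive")
        if not 0 < self.omega0 < 1:
            raise InvalidArgumentError("omega0 must lie in (0, 1)")
        if self.omega2 < 1:
            raise InvalidArgumentError("omega2 must be >= 1")
        if not (0 < self.p0 < 1 and 0 < self.p1 < 1 and self.p0 + self.p1 <= 1):
            raise InvalidArgumentError("p0, p1 must lie in (0,1) with p0 + p1 <= 1")
        if self.pi.shape != (codons.N_CODONS,) or np.any(self.pi < 0):
            raise InvalidArgumentError("pi must be 61 non-negative frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise InvalidArgumentError("pi must sum to 1")
        if self.scale <= 0:
            raise InvalidArgumentError("scale must be positive")

    @property
    def p2a(self) -> float:
        rest = 1.0 - self.p0 - self.p1
        return rest * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        rest = 1.0 - self.p0 - self.p1
        return rest * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])


#: omega assignments (background, foreground) per class; indices into
#: (omega0, 1, omega2)
_CLASS_OMEGAS = ((0, 0), (1, 1), (0, 2), (1, 2))
CLASS_NAMES = ("0", "1", "2a", "2b")


def _position_marginals(pi: np.ndarray) -> np.ndarray:
    """(3, 4) nucleotide marginals of a sense-codon distribution."""
    out = np.zeros((3, 4))
    nuc_index = {n: i for i, n in enumerate(codons.NUCLEOTIDES)}
    for c, p in zip(codons.CODONS, pi):
        for pos, n in enumerate(c):
            out[pos, nuc_index[n]] += p
    return out


def _f3x4_product(freqs: np.ndarray) -> np.ndarray:
    nuc_index = {n: i for i, n in enumerate(codons.NUCLEOTIDES)}
    pi = np.array(
        [
            freqs[0, nuc_index[c[0]]] * freqs[1, nuc_index[c[1]]] * freqs[2, nuc_index[c[2]]]
            for c in codons.CODONS
        ]
    )
    return pi / pi.sum()


#: position-specific nucleotide frequencies (A, C, G, T) typical of mammalian
#: coding sequence; the product law over sense codons is the simulation default
_DEFAULT_POSITION_FREQS = np.array(
    [
        [0.26, 0.22, 0.31, 0.21],
        [0.30, 0.23, 0.19, 0.28],
        [0.20, 0.28, 0.28, 0.24],
    ]
)

DEFAULT_PI = _f3x4_product(_DEFAULT_POSITION_FREQS)


# ---------------------------------------------------------------------------
# model building blocks


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Codon equilibrium frequencies from position-specific nucleotide usage.

    The F3x4 estimator: empirical nucleotide frequencies at each of the
    three codon positions, multiplied per codon, stop codons removed, and
    renormalized.  Position frequencies are floored at 1e-6 so nucleotides
    unseen at a position never zero out a codon observed in the data.
    """
    counts = np.zeros((3, 4))
    nuc_index = {n: i for i, n in enumerate(codons.NUCLEOTIDES)}
    for s in aln.seqs:
        for j in range(len(s) // 3):
            cod = s[3 * j : 3 * j + 3]
            if cod == codons.GAP_CODON:
                continue
            for pos, n in enumerate(cod):
                if n in nuc_index:
                    counts[pos, nuc_index[n]] += 1
    if counts.sum() == 0:
        raise InvalidArgumentError("alignment contains no unambiguous codons")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, 1e-6)
    freqs /= freqs.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nuc_index[c[0]]] * freqs[1, nuc_index[c[1]]] * freqs[2, nuc_index[c[2]]]
            for c in codons.CODONS
        ]
    )
    return pi / pi.sum()


def empirical_codon_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """F61-style equilibrium frequencies: observed codon usage, lightly smoothed.

    A pseudocount keeps every sense codon at positive frequency, which the
    reversible-generator machinery requires.  Unlike F3x4 this estimator is
    consistent for any stationary distribution, so it is the default for
    model fitting; F3x4 remains available for its smaller variance on short
    alignments with benign composition.
    """
    counts = np.full(codons.N_CODONS, pseudocount)
    for s in aln.seqs:
        for j in range(len(s) // 3):
            idx = codons.CODON_INDEX.get(s[3 * j : 3 * j + 3])
            if idx is not None:
                counts[idx] += 1.0
    return counts / counts.sum()


def pooled_codon_frequencies(
    alignments, estimator: str = "f3x4", pseudocount: float = 0.5
) -> np.ndarray:
    """Study-wide equilibrium frequencies pooled over many alignments.

    Per-gene frequency estimates from short alignments are noisy enough to
    distort the branch-site likelihood surface; pooling codon usage across
    the gene set (the analog of using genome-wide codon usage) removes most
    of that variance.  ``estimator`` selects F3x4 position-frequency pooling
    or smoothed empirical (F61) pooling.
    """
    alns = list(alignments.values()) if isinstance(alignments, dict) else list(alignments)
    if not alns:
        raise InvalidArgumentError("no alignments to pool")
    if estimator == "f3x4":
        counts = np.zeros((3, 4))
        nuc_index = {n: i for i, n in enumerate(codons.NUCLEOTIDES)}
        for a in alns:
            for s in a.seqs:
                for j in range(len(s) // 3):
                    cod = s[3 * j : 3 * j + 3]
                    if cod == codons.GAP_CODON:
                        continue
                    for pos, n in enumerate(cod):
                        if n in nuc_index:
                            counts[pos, nuc_index[n]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        freqs = np.maximum(freqs, 1e-6)
        freqs /= freqs.sum(axis=1, keepdims=True)
        return _f3x4_product(freqs)
    if estimator == "f61":
        counts = np.full(codons.N_CODONS, pseudocount)
        for a in alns:
            for s in a.seqs:
                for j in range(len(s) // 3):
                    idx = codons.CODON_INDEX.get(s[3 * j : 3 * j + 3])
                    if idx is not None:
                        counts[idx] += 1.0
        return counts / counts.sum()
    raise InvalidArgumentError(f"unknown estimator {estimator!r}")


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Goldman-Yang codon generator, unscaled; rows sum to zero.

    q_ij = pi_j * kappa^{transition} * omega^{nonsynonymous} for codon pairs
    differing at exactly one nucleotide; 0 otherwise.
    """
    if kappa <= 0 or omega < 0:
        raise InvalidArgumentError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    Q = np.where(codons.SINGLE_DIFF, pi[None, :], 0.0)
    Q = Q * np.where(codons.TRANSITION & codons.SINGLE_DIFF, kappa, 1.0)
    Q = Q * np.where(~codons.SYNONYMOUS & codons.SINGLE_DIFF, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to one, entries clipped into [0, 1]."""
    if t < 0:
        raise InvalidArgumentError("branch length must be non-negative")
    P = linalg.expm(Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def site_class_layout(params: BranchSiteParams) -> list[tuple[float, float, float]]:
    """The four Model A classes as (proportion, omega_background, omega_foreground)."""
    omegas = (params.omega0, 1.0, params.omega2)
    props = params.proportions
    return [(float(props[c]), omegas[bg], omegas[fg]) for c, (bg, fg) in enumerate(_CLASS_OMEGAS)]


class _SpectralGenerator:
    """Eigendecomposition of a reversible codon generator for fast expm."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(np.maximum(pi, 1e-300))
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # symmetric up to round-off by reversibility
        self.eigval, U = linalg.eigh(B, check_finite=False)
        self.left = U / d[:, None]
        self.right = (U * d[:, None]).T

    def expm(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.eigval * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


class _RateComponents:
    """Pi-dependent pieces of the codon generator, cached per frequency vector.

    The generator is linear in kappa and omega:
    Q = M_sv + kappa*M_st + omega*M_nv + kappa*omega*M_nt (plus the diagonal),
    and the corresponding pi-weighted fluxes give the mixture rate in closed
    form, so repeated optimizer evaluations avoid rebuilding masked arrays.
    """

    _cache: dict[bytes, "_RateComponents"] = {}

    def __init__(self, pi: np.ndarray):
        masks = {
            "sv": codons.SINGLE_DIFF & codons.SYNONYMOUS & ~codons.TRANSITION,
            "st": codons.SINGLE_DIFF & codons.SYNONYMOUS & codons.TRANSITION,
            "nv": codons.SINGLE_DIFF & ~codons.SYNONYMOUS & ~codons.TRANSITION,
            "nt": codons.SINGLE_DIFF & ~codons.SYNONYMOUS & codons.TRANSITION,
        }
        self.M = {k: np.where(m, pi[None, :], 0.0) for k, m in masks.items()}
        self.flux = {k: float(pi @ self.M[k].sum(axis=1)) for k in masks}

    @classmethod
    def get(cls, pi: np.ndarray) -> "_RateComponents":
        key = pi.tobytes()
        if key not in cls._cache:
            if len(cls._cache) > 32:
                cls._cache.clear()
            cls._cache[key] = cls(pi)
        return cls._cache[key]

    def generator(self, kappa: float, omega: float) -> np.ndarray:
        Q = (
            self.M["sv"]
            + kappa * self.M["st"]
            + omega * self.M["nv"]
            + (kappa * omega) * self.M["nt"]
        )
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def rate(self, kappa: float, omega: float) -> float:
        return (
            self.flux["sv"]
            + kappa * self.flux["st"]
            + omega * self.flux["nv"]
            + kappa * omega * self.flux["nt"]
        )


def mixture_rate_scale(params: BranchSiteParams) -> float:
    """Expected substitutions per codon per unit time of the background mixture.

    Uses the alternative-model class proportions with background omegas for
    both nested models, so branch lengths are on a common scale.
    """
    comp = _RateComponents.get(params.pi)
    w0 = params.p0 + params.p2a
    return w0 * comp.rate(params.kappa, params.omega0) + (1.0 - w0) * comp.rate(
        params.kappa, 1.0
    )


def scaled_generators(params: BranchSiteParams, omega2: float | None = None):
    """Generators for (omega0, 1, omega2), jointly scaled to unit mixture rate."""
    if omega2 is None:
        omega2 = params.omega2
    comp = _RateComponents.get(params.pi)
    rho = mixture_rate_scale(params)
    return [
        comp.generator(params.kappa, w) / rho for w in (params.omega0, 1.0, omega2)
    ]


# ---------------------------------------------------------------------------
# likelihood engine


class _PatternData:
    """Pattern-compressed alignment columns ordered like the tree's leaves."""

    def __init__(self, aln: CodonAlignment, tree: Phylogeny):
        order = []
        by_name = {sp: i for i, sp in enumerate(aln.species)}
        tree_leaves = tree.leaf_names
        if set(tree_leaves) != set(aln.species):
            raise SpeciesMismatchError(
                f"tree leaves {sorted(tree_leaves)} != alignment species {sorted(aln.species)}"
            )
        states = aln.state_matrix()
        self.leaf_nodes = tree.leaves
        for node in self.leaf_nodes:
            order.append(by_name[tree.labels[node]])
        states = states[order, :]
        patterns, inverse, counts = np.unique(
            states, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_leaves, S)
        self.inverse = inverse.ravel()
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        self._tips: dict[int, np.ndarray] | None = None

    def tip_partials(self) -> dict[int, np.ndarray]:
        if self._tips is None:
            self._tips = {}
            for row, node in enumerate(self.leaf_nodes):
                part = np.zeros((1, self.n_patterns, codons.N_CODONS))
                obs = self.patterns[row]
                missing = obs < 0
                part[0, missing, :] = 1.0
                idx = np.flatnonzero(~missing)
                part[0, idx, obs[idx]] = 1.0
                self._tips[node] = part
        return self._tips


def _all_class_logliks(
    data: _PatternData,
    tree: Phylogeny,
    params: BranchSiteParams,
    omega2: float,
) -> np.ndarray:
    """(4, S) per-class pattern log-likelihoods under the current parameters.

    All four Model A classes are pruned in one batched pass; the foreground
    branch uses the per-class foreground generator, every other branch the
    per-class background generator.
    """
    if tree.foreground is None:
        raise MissingForegroundError("tree has no foreground branch")
    gens = scaled_generators(params, omega2=omega2)
    spectral = [_SpectralGenerator(gens[0], params.pi), _SpectralGenerator(gens[1], params.pi)]
    # under the null (omega2 = 1) the foreground generator equals the neutral one
    spectral.append(spectral[1] if omega2 == 1.0 else _SpectralGenerator(gens[2], params.pi))
    tips = data.tip_partials()
    root = tree.root
    bg_regimes = [bg for bg, _ in _CLASS_OMEGAS]
    fg_regimes = [fg for _, fg in _CLASS_OMEGAS]

    def stacked_P(node: int) -> np.ndarray:
        regimes = fg_regimes if node == tree.foreground else bg_regimes
        t = tree.lengths[node] * params.scale
        cache = {r: spectral[r].expm(t) for r in set(regimes)}
        return np.stack([cache[r].T for r in regimes])  # (4, 61, 61) transposed

    S = data.n_patterns
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros((4, S))
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            partial[node] = tips[node]
            continue
        M = np.ones((4, S, codons.N_CODONS))
        for child in kids:
            M *= partial.pop(child) @ stacked_P(child)
        m = M.max(axis=2)
        safe = np.where(m > 0, m, 1.0)
        M /= safe[:, :, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(m > 0, np.log(safe), -np.inf)
        partial[node] = M
    lik = partial[root] @ params.pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def log_likelihood(
    aln: CodonAlignment,
    tree: Phylogeny,
    params: BranchSiteParams,
    model: str = "alternative",
) -> float:
    """Model A mixture log-likelihood; under the null, omega2 is forced to 1."""
    if model not in ("alternative", "null"):
        raise InvalidArgumentError(f"unknown model {model!r}")
    data = _PatternData(aln, tree)
    return _loglik_from_patterns(data, tree, params, model)


def _loglik_from_patterns(
    data: _PatternData, tree: Phylogeny, params: BranchSiteParams, model: str
) -> float:
    omega2 = 1.0 if model == "null" else params.omega2
    class_ll = _all_class_logliks(data, tree, params, omega2)
    props = params.proportions
    with np.errstate(divide="ignore"):
        logprops = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
    site_ll = logsumexp(class_ll + logprops[:, None], axis=0)
    return float(np.dot(data.counts, site_ll))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _logit(x: float) -> float:
    return float(np.log(x / (1.0 - x)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _pack(params: BranchSiteParams, model: str) -> np.ndarray:
    a = params.p0
    b = params.p1 / max(1.0 - params.p0, 1e-12)
    x = [
        np.log(params.kappa),
        _logit(np.clip(params.omega0, 1e-4, 1 - 1e-6)),
        _logit(np.clip(a, 1e-6, 1 - 1e-6)),
        _logit(np.clip(b, 1e-6, 1 - 1e-6)),
        np.log(params.scale),
    ]
    if model == "alternative":
        x.insert(2, np.log(max(params.omega2 - 1.0, 1e-8)))
    return np.array(x)


def _unpack(x: np.ndarray, model: str, pi: np.ndarray) -> BranchSiteParams:
    if model == "alternative":
        lk, lw0, lw2, za, zb, ls = x
        omega2 = 1.0 + np.exp(lw2)
    else:
        lk, lw0, za, zb, ls = x
        omega2 = 1.0
    a = np.clip(_expit(za), 1e-9, 1 - 1e-9)
    b = np.clip(_expit(zb), 1e-9, 1 - 1e-9)
    p0 = a
    p1 = (1.0 - a) * b
    return BranchSiteParams(
        kappa=float(np.exp(lk)),
        omega0=float(np.clip(_expit(lw0), 1e-6, 1 - 1e-9)),
        omega2=float(min(omega2, 999.0)),
        p0=float(p0),
        p1=float(max(p1, 1e-12)),
        pi=pi,
        scale=float(np.exp(ls)),
    )


_BOUNDS = {
    "kappa": (np.log(0.05), np.log(50.0)),
    "omega0": (-14.0, 7.0),
    "omega2": (np.log(1e-6), np.log(49.0)),
    "mix": (-14.0, 14.0),
    "scale": (np.log(1e-3), np.log(100.0)),
}


def _bounds(model: str) -> list[tuple[float, float]]:
    b = [_BOUNDS["kappa"], _BOUNDS["omega0"], _BOUNDS["mix"], _BOUNDS["mix"], _BOUNDS["scale"]]
    if model == "alternative":
        b.insert(2, _BOUNDS["omega2"])
    return b


def _random_start(rng: np.random.Generator, pi: np.ndarray) -> BranchSiteParams:
    d = rng.dirichlet((2.0, 2.0, 1.0))
    return BranchSiteParams(
        kappa=float(rng.uniform(0.5, 5.0)),
        omega0=float(rng.uniform(0.01, 0.9)),
        omega2=float(rng.uniform(1.0, 10.0)),
        p0=float(np.clip(d[0], 0.02, 0.96)),
        p1=float(np.clip(d[1], 0.02, 0.96)),
        pi=pi,
        scale=float(np.exp(rng.normal(0.0, 0.3))),
    )


_DEFAULT_START = dict(kappa=2.0, omega0=0.2, omega2=2.5, p0=0.55, p1=0.3, scale=1.0)


def fit_model(
    aln: CodonAlignment,
    tree: Phylogeny,
    foreground: int | str | None = None,
    model: str = "alternative",
    n_starts: int = 3,
    seed: int = 0,
    init: BranchSiteParams | None = None,
    maxfun: int = 600,
    freq_estimator: str = "f61",
    pi: np.ndarray | None = None,
) -> tuple[BranchSiteParams, float]:
    """Maximize the Model A likelihood by bounded quasi-Newton restarts.

    The first start is a fixed default (or ``init`` when given, e.g. the null
    MLE when fitting the alternative); the remaining ``n_starts - 1`` draw
    random initial points.  Equilibrium frequencies come from the data via
    the smoothed empirical (F61) estimator by default, or F3x4.  Returns the
    best (params, lnL).
    """
    if model not in ("alternative", "null"):
        raise InvalidArgumentError(f"unknown model {model!r}")
    if n_starts < 1:
        raise InvalidArgumentError("n_starts must be >= 1")
    if foreground is not None:
        tree = tree.with_foreground(foreground)
    if tree.foreground is None:
        raise MissingForegroundError("no foreground branch set")
    if pi is not None:
        pi = np.asarray(pi, dtype=float)
    elif freq_estimator == "f61":
        pi = empirical_codon_frequencies(aln)
    elif freq_estimator == "f3x4":
        pi = f3x4_frequencies(aln)
    else:
        raise InvalidArgumentError(f"unknown frequency estimator {freq_estimator!r}")
    data = _PatternData(aln, tree)
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        try:
            p = _unpack(x, model, pi)
            val = -_loglik_from_patterns(data, tree, p, model)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    starts: list[BranchSiteParams] = []
    base = replace(init, pi=pi) if init is not None else BranchSiteParams(pi=pi, **_DEFAULT_START)
    starts.append(base)
    if model == "alternative" and n_starts > 1:
        # a high-omega2 start with a modest class-2 mass guards against two
        # local optima: omega2 = 1 next to the null solution, and the
        # p2 -> 1 basin that absorbs the signal as mildly elevated omega
        f = 0.9 / (base.p0 + base.p1)
        starts.append(
            replace(base, omega2=8.0, p0=f * base.p0, p1=f * base.p1)
        )
    while len(starts) < n_starts:
        starts.append(_random_start(rng, pi))

    best: tuple[float, BranchSiteParams] | None = None
    failures = []
    for start in starts:
        x0 = _pack(start, model)
        try:
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=_bounds(model),
                options=dict(maxfun=maxfun, ftol=1e-9, gtol=1e-7),
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), _unpack(res.x, model, pi))
    if best is None:
        raise FitError("all optimizer starts failed", diagnostics=failures)
    return best[1], -best[0]


def fit_nested(
    aln: CodonAlignment,
    tree: Phylogeny,
    foreground: int | str | None = None,
    n_starts: int = 2,
    seed: int = 0,
    maxfun: int = 400,
    init: BranchSiteParams | None = None,
    freq_estimator: str = "f61",
    pi=None,
) -> tuple[BranchSiteParams, float, BranchSiteParams, float]:
    """Fit the null/alternative pair with cross-initialization.

    The alternative is initialized at the null MLE (plus a high-omega2
    start); the two fits are then cross-initialized from each other's MLE
    until neither improves, so the likelihood-ratio statistic never reflects
    one model landing in a local optimum the other escaped — whenever the
    alternative leads, the null is given the chance to chase it into the
    same basin with omega2 = 1.  Returns (null_mle, lnl_null, alt_mle,
    lnl_alt) with lnl_alt >= lnl_null by construction.
    """
    if foreground is not None:
        tree = tree.with_foreground(foreground)
    null_mle, lnl_null = fit_model(
        aln, tree, model="null", n_starts=max(1, n_starts - 1), seed=seed,
        maxfun=maxfun, init=init, freq_estimator=freq_estimator, pi=pi,
    )
    alt_mle, lnl_alt = fit_model(
        aln, tree, model="alternative", n_starts=n_starts, seed=seed + 1,
        init=null_mle, maxfun=maxfun, freq_estimator=freq_estimator, pi=pi,
    )
    tol = 5e-3
    # the initial alternative fit was already initialized from the current null
    last_alt_chased = None
    last_null_chased = lnl_null
    for round_ in range(3):
        progressed = False
        if lnl_alt - lnl_null > tol and lnl_alt != last_alt_chased:
            # the alternative leads: give the null a chance to follow it into
            # the same basin with omega2 = 1
            last_alt_chased = lnl_alt
            null2, lnl_null2 = fit_model(
                aln, tree, model="null", n_starts=1, seed=seed + 2 + round_,
                init=alt_mle, maxfun=maxfun, freq_estimator=freq_estimator, pi=pi,
            )
            if lnl_null2 > lnl_null + 1e-6:
                null_mle, lnl_null = null2, lnl_null2
                progressed = True
        if lnl_null > lnl_alt - tol and lnl_null != last_null_chased:
            # the null caught up or leads from a basin the alternative has
            # not explored yet
            last_null_chased = lnl_null
            alt2, lnl_alt2 = fit_model(
                aln, tree, model="alternative", n_starts=2, seed=seed + 7 + round_,
                init=null_mle, maxfun=maxfun, freq_estimator=freq_estimator, pi=pi,
            )
            if lnl_alt2 > lnl_alt + 1e-6:
                alt_mle, lnl_alt = alt2, lnl_alt2
                progressed = True
        if not progressed:
            break
    if lnl_alt < lnl_null:
        # boundary case: the alternative contains the null, so its optimum can
        # never be genuinely lower; report the null solution with omega2 = 1
        alt_mle = replace(null_mle, omega2=1.0)
        lnl_alt = lnl_null
    return null_mle, lnl_null, alt_mle, lnl_alt


def lrt(
    lnl_alt: float, lnl_null: float, null_distribution: str = "chi2"
) -> tuple[float, float]:
    """Likelihood-ratio statistic and p-value.

    ``null_distribution="chi2"`` refers 2*(lnL_alt - lnL_null), clamped at
    zero, to chi-square(1) — the conservative standard.  ``"mixture"`` uses
    the 1/2 point-mass-at-0 + 1/2 chi-square(1) boundary mixture.
    """
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    if null_distribution == "chi2":
        p = float(stats.chi2.sf(stat, df=1))
    elif null_distribution == "mixture":
        p = 1.0 if stat == 0.0 else float(0.5 * stats.chi2.sf(stat, df=1))
    else:
        raise InvalidArgumentError(f"unknown null distribution {null_distribution!r}")
    return stat, min(p, 1.0)


def site_posteriors(
    aln: CodonAlignment,
    tree: Phylogeny,
    mle: BranchSiteParams,
    threshold: float = 0.5,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Naive empirical Bayes class posteriors per site under the fitted model.

    Returns an (n_codons, 4) posterior array (classes 0, 1, 2a, 2b) and the
    selected sites: 0-based positions whose posterior of belonging to class
    2a or 2b reaches ``threshold``.
    """
    data = _PatternData(aln, tree)
    class_ll = _all_class_logliks(data, tree, mle, mle.omega2)
    props = mle.proportions
    with np.errstate(divide="ignore"):
        logprops = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
    joint = class_ll + logprops[:, None]
    post = np.exp(joint - logsumexp(joint, axis=0, keepdims=True)).T  # (S, 4)
    per_site = post[data.inverse]
    p_sel = per_site[:, 2] + per_site[:, 3]
    selected = [(int(i), float(p_sel[i])) for i in np.flatnonzero(p_sel >= threshold)]
    return per_site, selected
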