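"""Young-vs-old differential expression and the antagonistic-pleiotropy tests.

Per species, genes are tested for differential expression between age
groups with a minimal negative-binomial Wald test (median-of-ratios size
factors, moment dispersion estimates shrunk toward a fitted
mean-dispersion trend).  Genes regulated (q <= 0.1) in both species are
placed in fold-change quadrants; quadrant I (down with age in the
long-lived species A, up in the short-lived species B) is the
antagonistic-pleiotropy pattern.  PSG excess in quadrant I is tested with a
one-sided Fisher exact test, and the two per-species directional Fisher
p-values are combined with the Lancaster procedure.

Externally produced fold-change/q tables can be substituted for the
built-in DE stage: every downstream operation consumes plain DeRecord
lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from psgscan.errors import InvalidArgumentError, NormalizationError
from psgscan.screening import bh_fdr

QUADRANTS = ("I", "II", "III", "IV")


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts for one species with young/old labels."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    condition: list[str]
    species: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise InvalidArgumentError("count matrix shape mismatch")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("negative counts")
        if set(self.condition) - {"young", "old"}:
            raise InvalidArgumentError("conditions must be 'young' or 'old'")
        for cond in ("young", "old"):
            if sum(c == cond for c in self.condition) < 2:
                raise InvalidArgumentError(f"need >= 2 '{cond}' samples")

    def group_columns(self, cond: str) -> np.ndarray:
        return np.flatnonzero([c == cond for c in self.condition])


@dataclass
class DeRecord:
    gene: str
    lfc: float  # log2 fold-change, old vs young
    p: float
    q: float
    regulated: bool

    def __post_init__(self):
        if self.regulated and self.q > 0.1:
            raise InvalidArgumentError("regulated flag requires q <= 0.1")


@dataclass
class QuadrantTable:
    """Genes regulated in both species, placed by fold-change sign pair.

    Quadrant I = (LFC_A < 0, LFC_B > 0), II = (-,-), III = (+,-), IV = (+,+).
    """

    quadrant: dict[str, str]  # gene -> quadrant
    psg: dict[str, bool]
    counts: dict[str, dict[str, int]] = field(init=False)  # quadrant -> {psg, other}

    def __post_init__(self):
        bad = set(self.quadrant.values()) - set(QUADRANTS)
        if bad:
            raise InvalidArgumentError(f"unknown quadrants {bad}")
        self.counts = {q: {"psg": 0, "other": 0} for q in QUADRANTS}
        for gene, q in self.quadrant.items():
            key = "psg" if self.psg.get(gene, False) else "other"
            self.counts[q][key] += 1

    @property
    def n_genes(self) -> int:
        return len(self.quadrant)


# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    factor_j = median over genes expressed in every sample of
    count_gj / geometric_mean_g(counts).
    """
    k = counts.counts.astype(float)
    expressed = np.all(k > 0, axis=1)
    if not np.any(expressed):
        raise NormalizationError("no gene has nonzero counts in every sample")
    logk = np.log(k[expressed])
    log_geo = logk.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logk - log_geo, axis=0))
    return factors / np.exp(np.log(factors).mean())


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu by least squares on genes with usable moments."""
    ok = (mu > 0) & np.isfinite(alpha) & (alpha > 0)
    if ok.sum() < 10:
        return np.full_like(mu, max(np.nanmedian(alpha[ok]) if ok.any() else 0.1, 1e-8))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mu, 1e-8)
    return np.clip(trend, 1e-8, 10.0)


def de_test(counts: CountMatrix, q_threshold: float = 0.1) -> list[DeRecord]:
    """Negative-binomial Wald test of old vs young per gene.

    Moment dispersion per gene (pooled within-group variance of normalized
    counts), floored at 1e-8 and shrunk halfway toward the fitted
    mean-dispersion trend; the Wald z uses the delta-method variance of the
    log2 group-mean ratio and a normal reference.  All-zero genes get
    LFC 0, p 1.
    """
    sf = size_factors(counts)
    norm = counts.counts / sf[None, :]
    yi = counts.group_columns("young")
    oi = counts.group_columns("old")
    ny, no = yi.size, oi.size
    mu_y = norm[:, yi].mean(axis=1)
    mu_o = norm[:, oi].mean(axis=1)
    var_y = norm[:, yi].var(axis=1, ddof=1)
    var_o = norm[:, oi].var(axis=1, ddof=1)
    mu_pool = (ny * mu_y + no * mu_o) / (ny + no)
    var_pool = ((ny - 1) * var_y + (no - 1) * var_o) / (ny + no - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_pool - mu_pool) / mu_pool**2
    alpha_trend = _dispersion_trend(mu_pool, alpha_mom)
    alpha = np.maximum(0.5 * np.maximum(alpha_mom, 1e-8) + 0.5 * alpha_trend, 1e-8)

    inv_sf_y = np.mean(1.0 / sf[yi])
    inv_sf_o = np.mean(1.0 / sf[oi])
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mu_o / mu_y)
        # delta method on log2 of each group mean of normalized NB counts
        v_log_y = (mu_y * inv_sf_y + alpha * mu_y**2) / (ny * mu_y**2 * np.log(2) ** 2)
        v_log_o = (mu_o * inv_sf_o + alpha * mu_o**2) / (no * mu_o**2 * np.log(2) ** 2)
        se = np.sqrt(v_log_y + v_log_o)
        z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    dead = (mu_y <= 0) | (mu_o <= 0) | ~np.isfinite(lfc) | ~np.isfinite(p)
    lfc = np.where(dead, 0.0, lfc)
    p = np.where(dead, 1.0, p)
    q = bh_fdr(p)
    return [
        DeRecord(
            gene=g,
            lfc=float(lfc[i]),
            p=float(p[i]),
            q=float(q[i]),
            regulated=bool(q[i] <= q_threshold and not dead[i]),
        )
        for i, g in enumerate(counts.genes)
    ]


# ---------------------------------------------------------------------------


def classify_quadrants(
    de_a: list[DeRecord], de_b: list[DeRecord], psgs: set[str]
) -> QuadrantTable:
    """Place genes regulated in both species into fold-change quadrants.

    Genes regulated in only one species are excluded (the analog of genes
    with insufficient expression in one species); genes with an exact zero
    fold-change among the regulated are excluded as direction-less.
    """
    a = {r.gene: r for r in de_a}
    b = {r.gene: r for r in de_b}
    quadrant: dict[str, str] = {}
    for gene in a.keys() & b.keys():
        ra, rb = a[gene], b[gene]
        if not (ra.regulated and rb.regulated):
            continue
        if ra.lfc == 0.0 or rb.lfc == 0.0:
            continue
        if ra.lfc < 0:
            quadrant[gene] = "I" if rb.lfc > 0 else "II"
        else:
            quadrant[gene] = "IV" if rb.lfc > 0 else "III"
    return QuadrantTable(quadrant=quadrant, psg={g: g in psgs for g in quadrant})


def quadrant_fisher(table: QuadrantTable) -> float:
    """One-sided Fisher exact p for PSG excess in quadrant I vs II+III+IV."""
    a = table.counts["I"]["psg"]
    b = sum(table.counts[q]["psg"] for q in ("II", "III", "IV"))
    c = table.counts["I"]["other"]
    d = sum(table.counts[q]["other"] for q in ("II", "III", "IV"))
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate quadrant table margin; p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def lancaster_combine(p: list[float], w: list[float]) -> float:
    """Lancaster's weighted combination of independent p-values.

    Each p_i maps to the upper-tail chi-square quantile with df = w_i; the
    sum is referred to chi-square with df = sum(w).  Equal weights of 2
    recover Fisher's method.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != w.shape or p.size == 0:
        raise InvalidArgumentError("p and w must be equal-length, non-empty")
    if np.any(w <= 0):
        raise InvalidArgumentError("weights must be positive")
    if np.any((p <= 0) | (p > 1)):
        if np.any(p == 0):
            warnings.warn("p-value of 0 clamped to machine minimum")
            p = np.maximum(p, np.finfo(float).tiny)
        if np.any((p < 0) | (p > 1)):
            raise InvalidArgumentError("p-values must lie in (0, 1]")
    t = np.sum(stats.chi2.isf(p, df=w))
    return float(stats.chi2.sf(t, df=w.sum()))


def directionality_test(
    de_a: list[DeRecord], de_b: list[DeRecord], psgs: set[str]
) -> dict[str, float]:
    """Do PSGs prefer the longevity-consistent direction during aging?

    Species A (long-lived): one-sided Fisher test for PSG excess among the
    down-regulated within A's regulated genes.  Species B (short-lived):
    same for up-regulation.  The two p-values are combined with Lancaster
    weights (2, 2), i.e. Fisher's method.  Returns the per-species and
    combined p-values.
    """

    def one_sided(de: list[DeRecord], want_negative: bool) -> float:
        reg = [r for r in de if r.regulated and r.lfc != 0.0]
        if not any(r.gene in psgs for r in reg):
            return 1.0
        a = sum(r.gene in psgs and (r.lfc < 0) == want_negative for r in reg)
        b = sum(r.gene in psgs and (r.lfc < 0) != want_negative for r in reg)
        c = sum(r.gene not in psgs and (r.lfc < 0) == want_negative for r in reg)
        d = sum(r.gene not in psgs and (r.lfc < 0) != want_negative for r in reg)
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])

    p_a = one_sided(de_a, want_negative=True)
    p_b = one_sided(de_b, want_negative=False)
    return {
        "p_down_in_a": p_a,
        "p_up_in_b": p_b,
        "p_combined": lancaster_combine([p_a, p_b], [2.0, 2.0]),
    }
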