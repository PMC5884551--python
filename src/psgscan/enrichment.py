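"""Term-level statistics: hypergeometric enrichment, fold-change perturbation
tests, category unions and union-overlap tests.

Annotation is a flat gene-to-term table over an explicit gene universe; no
ontology-graph propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from psgscan.errors import InvalidArgumentError, UnknownTermError
from psgscan.screening import bh_fdr


@dataclass
class AnnotationMap:
    """Gene-term membership with consistent forward/inverse maps."""

    gene_terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    term_genes: dict[str, set[str]] = field(init=False)

    def __post_init__(self):
        if not self.universe:
            self.universe = set(self.gene_terms)
        missing = set(self.gene_terms) - self.universe
        if missing:
            raise InvalidArgumentError(
                f"{len(missing)} annotated genes outside the universe"
            )
        self.term_genes = {}
        for gene, terms in self.gene_terms.items():
            for term in terms:
                self.term_genes.setdefault(term, set()).add(gene)

    @classmethod
    def from_pairs(cls, pairs, universe=None) -> "AnnotationMap":
        gene_terms: dict[str, set[str]] = {}
        for gene, term in pairs:
            gene_terms.setdefault(gene, set()).add(term)
        return cls(gene_terms=gene_terms, universe=set(universe) if universe else set())


@dataclass
class EnrichmentRecord:
    term: str
    overlap: int
    set_size: int
    term_size: int
    universe_size: int
    p: float
    q: float = float("nan")
    direction: str | None = None  # up | down for fold-change tests

    def __post_init__(self):
        if self.overlap > min(self.set_size, self.term_size):
            raise InvalidArgumentError("overlap exceeds set sizes")


# ---------------------------------------------------------------------------


def _hypergeom_upper(overlap: int, universe: int, term: int, drawn: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, term, drawn)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, term, drawn))


def hypergeom_enrich(
    genes: set[str], ann: AnnotationMap, q_threshold: float = 0.1
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric overrepresentation per term, BH-corrected."""
    if not genes <= ann.universe:
        raise InvalidArgumentError("gene set extends beyond the universe")
    if not genes:
        return []
    n_universe = len(ann.universe)
    records = []
    for term in sorted(ann.term_genes):
        members = ann.term_genes[term]
        overlap = len(genes & members)
        p = _hypergeom_upper(overlap, n_universe, len(members), len(genes))
        records.append(
            EnrichmentRecord(
                term=term, overlap=overlap, set_size=len(genes),
                term_size=len(members), universe_size=n_universe, p=p,
            )
        )
    qs = bh_fdr([r.p for r in records])
    for r, q in zip(records, qs):
        r.q = float(q)
    return records


def fc_set_test(
    lfc: dict[str, float], ann: AnnotationMap, min_members: int = 2
) -> list[EnrichmentRecord]:
    """Directional term perturbation from per-gene log2 fold-changes.

    Per term and direction, a one-sided Welch t-test compares member LFCs
    against non-member LFCs; 'down' tests for a lower member mean, 'up' for
    a higher one.  BH correction is applied within each direction.  Terms
    with fewer than ``min_members`` scored members are skipped.
    """
    scored = {g: x for g, x in lfc.items() if g in ann.universe}
    records: list[EnrichmentRecord] = []
    for direction, alternative in (("down", "less"), ("up", "greater")):
        batch = []
        for term in sorted(ann.term_genes):
            members = [scored[g] for g in ann.term_genes[term] if g in scored]
            others = [x for g, x in scored.items() if g not in ann.term_genes[term]]
            if len(members) < min_members or len(others) < min_members:
                continue
            res = stats.ttest_ind(
                members, others, equal_var=False, alternative=alternative
            )
            batch.append(
                EnrichmentRecord(
                    term=term, overlap=len(members), set_size=len(scored),
                    term_size=len(ann.term_genes[term]),
                    universe_size=len(ann.universe), p=float(res.pvalue),
                    direction=direction,
                )
            )
        qs = bh_fdr([r.p for r in batch])
        for r, q in zip(batch, qs):
            r.q = float(q)
        records.extend(batch)
    return records


def category_union(ann: AnnotationMap, terms: list[str]) -> set[str]:
    """Union of member genes over a list of terms (e.g. one summary category)."""
    out: set[str] = set()
    for term in terms:
        if term not in ann.term_genes:
            raise UnknownTermError(term)
        out |= ann.term_genes[term]
    return out


def overlap_test(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """One-sided Fisher exact p for excess overlap of two gene sets."""
    if not universe:
        raise InvalidArgumentError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise InvalidArgumentError("sets extend beyond the universe")
    overlap = len(set_a & set_b)
    return _hypergeom_upper(overlap, len(universe), len(set_b), len(set_a))
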