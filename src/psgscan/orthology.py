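"""Reciprocal-best-hit orthology with isoform selection and codon alignments.

Best bidirectional hits are computed against an anchor species using exact
Smith-Waterman-Gotoh local protein alignment (BLOSUM62, gap open 11,
extend 1) — desk-scale catalogs make a heuristic search unnecessary while
preserving the reciprocal-best-hit semantics.  One representative isoform
per species per ortholog group is chosen by highest alignment score to the
anchor's representative, and groups can be merged across a transcriptome-
and a genome-derived assembly of the same species (transcriptome CDSs take
precedence).

Protein profile alignment for the per-group codon alignments is progressive
(anchor first, then descending anchor similarity) under the same scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from psgscan import codons
from psgscan.errors import (
    FrameError,
    InsufficientTaxaError,
    InvalidArgumentError,
)
from psgscan.selection import CodonAlignment

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


@dataclass
class CdsRecord:
    """One coding sequence: gene, species, isoform, in-frame nucleotides."""

    gene: str
    species: str
    isoform: str
    seq: str
    source: str = "transcriptome"

    def __post_init__(self):
        self.seq = self.seq.upper()
        if len(self.seq) % 3:
            raise InvalidArgumentError(
                f"{self.species}:{self.gene}:{self.isoform}: length not divisible by 3"
            )
        if set(self.seq) - set("ACGTN"):
            raise InvalidArgumentError("CDS alphabet must be A/C/G/T/N")
        if self.source not in ("transcriptome", "genome"):
            raise InvalidArgumentError("source must be transcriptome or genome")

    @property
    def coding_seq(self) -> str:
        """CDS with an optional terminal stop codon trimmed."""
        if self.seq[-3:] in codons.STOP_CODONS:
            return self.seq[:-3]
        return self.seq

    @property
    def protein(self) -> str:
        return translate_cds(self.seq)


@dataclass
class OrthologGroup:
    """One anchor gene with its chosen ortholog per species."""

    group_id: str
    anchor_gene: str
    anchor_species: str
    chosen: dict[str, CdsRecord] = field(default_factory=dict)
    candidates: dict[str, list[CdsRecord]] = field(default_factory=dict)

    def __post_init__(self):
        if self.anchor_species not in self.candidates and self.anchor_species not in self.chosen:
            raise InvalidArgumentError("anchor species missing from group")


# ---------------------------------------------------------------------------


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS with the universal code.

    A terminal stop is dropped; an internal stop raises FrameError; codons
    containing N translate to 'X'.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise InvalidArgumentError("CDS length not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise FrameError(f"internal stop codon at codon {protein.index('*')}")
    return protein


def _aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_LOCAL = _aligner("local")


def align_pair(a: str, b: str) -> tuple[float, tuple[str, str]]:
    """Optimal local protein alignment score and one optimal aligned pair.

    Smith-Waterman-Gotoh under BLOSUM62 with affine gaps (open 11, extend
    1); the empty alignment scores 0, so scores are never negative.
    """
    if not a or not b:
        raise InvalidArgumentError("empty sequence")
    alignments = _LOCAL.align(a, b)
    score = float(alignments.score)
    if score <= 0:
        return max(score, 0.0), ("", "")
    top = alignments[0]
    return score, (str(top[0]), str(top[1]))


def pair_score(a: str, b: str) -> float:
    if not a or not b:
        raise InvalidArgumentError("empty sequence")
    return max(float(_LOCAL.score(a, b)), 0.0)


# ---------------------------------------------------------------------------


def _gene_scores(
    records_a: list[CdsRecord], records_b: list[CdsRecord]
) -> float:
    """Isoform-maximal protein score between two genes."""
    best = 0.0
    for ra in records_a:
        pa = ra.protein
        for rb in records_b:
            best = max(best, pair_score(pa, rb.protein))
    return best


def _by_gene(catalog: list[CdsRecord]) -> dict[str, list[CdsRecord]]:
    out: dict[str, list[CdsRecord]] = {}
    for rec in catalog:
        out.setdefault(rec.gene, []).append(rec)
    return out


def assign_orthologs(
    catalogs: dict[str, list[CdsRecord]],
    anchor: str,
    grouping: dict[str, str] | None = None,
) -> list[OrthologGroup]:
    """Reciprocal best hits of every species' genes against the anchor.

    A species gene joins an anchor gene's group iff each is the other's
    best-scoring hit (scores maximized over isoform pairs).  Ties break
    deterministically by (score, lexicographic gene id).  ``grouping``
    optionally maps anchor genes to externally defined group ids; otherwise
    every anchor gene seeds its own group.
    """
    if anchor not in catalogs:
        raise InvalidArgumentError(f"anchor species {anchor!r} not in catalogs")
    anchor_genes = _by_gene(catalogs[anchor])
    groups = {
        gene: OrthologGroup(
            group_id=(grouping or {}).get(gene, gene),
            anchor_gene=gene,
            anchor_species=anchor,
            candidates={anchor: recs},
        )
        for gene, recs in sorted(anchor_genes.items())
    }
    for species in sorted(catalogs):
        if species == anchor:
            continue
        sp_genes = _by_gene(catalogs[species])
        scores = {
            (sg, ag): _gene_scores(sp_recs, anchor_genes[ag])
            for sg, sp_recs in sp_genes.items()
            for ag in anchor_genes
        }

        def best(candidates, key):
            # highest score, then lexicographically smallest id
            return max(candidates, key=lambda g: (key(g), [-ord(c) for c in g]))

        best_anchor = {
            sg: best(anchor_genes, lambda ag: scores[(sg, ag)]) for sg in sp_genes
        }
        best_species = {
            ag: best(sp_genes, lambda sg: scores[(sg, ag)]) for ag in anchor_genes
        }
        for sg, ag in sorted(best_anchor.items()):
            if best_species[ag] == sg and scores[(sg, ag)] > 0:
                groups[ag].candidates[species] = sp_genes[sg]
    return list(groups.values())


def select_isoforms(group: OrthologGroup) -> OrthologGroup:
    """Choose one representative isoform per species.

    The anchor representative is its longest CDS (ties: lexicographic
    isoform id); every other species picks the isoform with the highest
    local alignment score to the anchor representative, breaking ties by
    longest CDS then lexicographic isoform id.
    """
    for species, cands in group.candidates.items():
        if not cands:
            raise InvalidArgumentError(f"empty candidate list for {species}")
    anchor_cands = group.candidates[group.anchor_species]
    anchor_rep = min(anchor_cands, key=lambda r: (-len(r.seq), r.isoform))
    chosen = {group.anchor_species: anchor_rep}
    anchor_protein = anchor_rep.protein
    for species in sorted(group.candidates):
        if species == group.anchor_species:
            continue
        chosen[species] = min(
            group.candidates[species],
            key=lambda r: (-pair_score(r.protein, anchor_protein), -len(r.seq), r.isoform),
        )
    return replace(group, chosen=chosen)


def merge_dual_assemblies(
    groups_tx: list[OrthologGroup],
    groups_gen: list[OrthologGroup],
    species: str,
) -> list[OrthologGroup]:
    """Merge a transcriptome and a genome assembly of one species.

    Per anchor gene, the species' transcriptome-derived candidates are kept
    when present; genome-derived candidates fill in only where the
    transcriptome run contributed none.  Other species' candidates follow
    the transcriptome run.
    """
    gen_by_anchor = {g.anchor_gene: g for g in groups_gen}
    merged = []
    for group in groups_tx:
        out = replace(
            group,
            chosen=dict(group.chosen),
            candidates={sp: list(recs) for sp, recs in group.candidates.items()},
        )
        if species not in out.candidates:
            gen = gen_by_anchor.get(group.anchor_gene)
            if gen is not None and species in gen.candidates:
                out.candidates[species] = [
                    replace(r, source="genome") for r in gen.candidates[species]
                ]
        merged.append(out)
    return merged


# ---------------------------------------------------------------------------
# progressive protein alignment and back-translation


def _profile_align(profile: list[str], seq: str) -> tuple[list[str], str]:
    """Global affine-gap alignment of one protein against an aligned profile.

    Column-vs-residue score is the mean BLOSUM62 score over the profile's
    non-gap residues (gap residues contribute 0).  Returns the re-gapped
    profile rows and the gapped new sequence.
    """
    n_rows = len(profile)
    ncol = len(profile[0]) if profile else 0
    m = len(seq)
    col_score = np.zeros((ncol, m))
    for j in range(ncol):
        residues = [row[j] for row in profile if row[j] != "-"]
        if residues:
            for i, aa in enumerate(seq):
                col_score[j, i] = float(
                    np.mean([BLOSUM62[r, aa] for r in residues])
                )
    NEG = -1e9
    # Gotoh three-state DP over (profile columns) x (sequence residues)
    M = np.full((ncol + 1, m + 1), NEG)
    X = np.full_like(M, NEG)  # gap in sequence (profile column unmatched)
    Y = np.full_like(M, NEG)  # gap in profile
    M[0, 0] = 0.0
    for j in range(1, ncol + 1):
        X[j, 0] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    for i in range(1, m + 1):
        Y[0, i] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, ncol + 1):
        for i in range(1, m + 1):
            M[j, i] = max(M[j - 1, i - 1], X[j - 1, i - 1], Y[j - 1, i - 1]) + col_score[j - 1, i - 1]
            X[j, i] = max(M[j - 1, i] - GAP_OPEN, X[j - 1, i] - GAP_EXTEND)
            Y[j, i] = max(M[j, i - 1] - GAP_OPEN, Y[j, i - 1] - GAP_EXTEND)
    # traceback
    j, i = ncol, m
    state = int(np.argmax([M[j, i], X[j, i], Y[j, i]]))
    ops = []  # 0 = match column, 1 = profile column vs gap, 2 = gap vs residue
    while j > 0 or i > 0:
        if j == 0:
            ops.append(2); i -= 1; continue
        if i == 0:
            ops.append(1); j -= 1; continue
        if state == 0:
            prev = int(np.argmax([M[j - 1, i - 1], X[j - 1, i - 1], Y[j - 1, i - 1]]))
            ops.append(0); j -= 1; i -= 1; state = prev
        elif state == 1:
            prev = 0 if M[j - 1, i] - GAP_OPEN >= X[j - 1, i] - GAP_EXTEND else 1
            ops.append(1); j -= 1; state = prev
        else:
            prev = 0 if M[j, i - 1] - GAP_OPEN >= Y[j, i - 1] - GAP_EXTEND else 2
            ops.append(2); i -= 1; state = prev
    ops.reverse()
    new_rows = ["" for _ in range(n_rows)]
    new_seq = []
    j = i = 0
    for op in ops:
        if op == 0:
            for r in range(n_rows):
                new_rows[r] += profile[r][j]
            new_seq.append(seq[i])
            j += 1; i += 1
        elif op == 1:
            for r in range(n_rows):
                new_rows[r] += profile[r][j]
            new_seq.append("-")
            j += 1
        else:
            for r in range(n_rows):
                new_rows[r] += "-"
            new_seq.append(seq[i])
            i += 1
    return new_rows, "".join(new_seq)


def build_codon_alignment(
    group: OrthologGroup,
    max_column_gap: float = 0.5,
    min_row_coverage: float = 0.5,
) -> CodonAlignment:
    """Progressive protein alignment of the chosen CDSs, back-translated.

    Sequences join the profile in order of descending similarity to the
    anchor; columns with more than ``max_column_gap`` gaps are removed and
    species retaining fewer than ``min_row_coverage`` non-gap codons are
    dropped.  Ungapping any surviving row reproduces its input CDS (minus
    the trimmed terminal stop) unless the column filter removed sites.
    """
    chosen = group.chosen or select_isoforms(group).chosen
    if len(chosen) < 2:
        raise InsufficientTaxaError("fewer than two species in group")
    anchor = group.anchor_species
    proteins = {sp: rec.protein for sp, rec in chosen.items()}
    order = [anchor] + sorted(
        (sp for sp in chosen if sp != anchor),
        key=lambda sp: (-pair_score(proteins[sp], proteins[anchor]), sp),
    )
    profile = [proteins[order[0]]]
    for sp in order[1:]:
        profile, new = _profile_align(profile, proteins[sp])
        profile.append(new)
    # back-translate to codons
    rows = {}
    for sp, aligned in zip(order, profile):
        cds = chosen[sp].coding_seq
        out, k = [], 0
        for aa in aligned:
            if aa == "-":
                out.append(codons.GAP_CODON)
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows[sp] = out
    ncol = len(profile[0])
    n_sp = len(order)
    keep_cols = [
        j for j in range(ncol)
        if sum(rows[sp][j] == codons.GAP_CODON for sp in order) <= max_column_gap * n_sp
    ]
    filtered = {sp: [rows[sp][j] for j in keep_cols] for sp in order}
    surviving = [
        sp for sp in order
        if keep_cols
        and sum(c != codons.GAP_CODON for c in filtered[sp]) >= min_row_coverage * len(keep_cols)
    ]
    if len(surviving) < 2:
        raise InsufficientTaxaError("fewer than two species survive alignment filters")
    return CodonAlignment(
        species=surviving,
        seqs=["".join(filtered[sp]) for sp in surviving],
    )
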