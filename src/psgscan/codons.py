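"""Universal genetic-code tables shared by the codon model and the simulators.

The 61 sense codons are kept in a fixed lexicographic order; every module
that exchanges codon-state indices relies on that order.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # universal code

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: the 61 sense codons, lexicographic
CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)
N_CODONS = len(CODONS)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: amino acid per sense codon, aligned with CODONS
AMINO_ACIDS: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in CODONS)

GAP_CODON = "---"

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition (A<->G, C<->T)."""
    return (a in _PURINES) == (b in _PURINES)


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify every ordered sense-codon pair differing at exactly one position.

    Returns boolean (61, 61) arrays: single-difference mask, transition mask,
    synonymous mask (the latter two defined only where the first is True).
    """
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = is_transition(*diffs[0])
            synonymous[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return single, transition, synonymous

SINGLE_DIFF, TRANSITION, SYNONYMOUS = _pair_tables()
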