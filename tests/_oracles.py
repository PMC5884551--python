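"""Independent oracles used by the test suite.

The likelihood oracle sums the joint probability over *every* assignment of
codon states to internal nodes (an exhaustive enumeration expressed as a
tensor contraction), bypassing the pruning recursion entirely.  Transition
matrices come straight from scipy's expm rather than the package's spectral
path.
"""

import math

import numpy as np
from scipy.linalg import expm

from psgscan import codons
from psgscan.selection import _CLASS_OMEGAS, scaled_generators


def enumeration_loglik(aln, tree, params, model):
    """Site-wise mixture log-likelihood by exhaustive internal-state sums."""
    omega2 = 1.0 if model == "null" else params.omega2
    gens = scaled_generators(params, omega2=omega2)
    P = {}
    for regime in range(3):
        for node in range(tree.n_nodes):
            if node != tree.root:
                P[(node, regime)] = expm(gens[regime] * tree.lengths[node] * params.scale)

    states = aln.state_matrix()
    leaf_of = {tree.labels[n]: n for n in tree.leaves}
    internals = [n for n in range(tree.n_nodes) if tree.children[n]]
    axis = {n: i for i, n in enumerate(internals)}
    props = params.proportions

    total = 0.0
    for site in range(aln.n_codons):
        site_lik = 0.0
        for c, (bg, fg) in enumerate(_CLASS_OMEGAS):
            operands, scripts = [], []
            operands.append(params.pi)
            scripts.append([axis[tree.root]])
            for node in range(tree.n_nodes):
                if node == tree.root:
                    continue
                regime = fg if node == tree.foreground else bg
                p_ax = axis[int(tree.parent[node])]
                if tree.children[node]:  # internal branch
                    operands.append(P[(node, regime)])
                    scripts.append([p_ax, axis[node]])
                else:
                    obs = states[aln.species.index(tree.labels[node]), site]
                    if obs < 0:  # missing data: sums to one over states
                        continue
                    operands.append(P[(node, regime)][:, obs])
                    scripts.append([p_ax])
            args = [x for pair in zip(operands, scripts) for x in pair]
            site_lik += props[c] * float(np.einsum(*args, []))
        total += math.log(site_lik)
    return total


def hypergeom_tail(overlap, universe, term, drawn):
    """P(X >= overlap) by explicit summation of the hypergeometric pmf."""
    total = 0.0
    for k in range(overlap, min(term, drawn) + 1):
        if drawn - k > universe - term:
            continue
        total += (
            math.comb(term, k)
            * math.comb(universe - term, drawn - k)
            / math.comb(universe, drawn)
        )
    return total


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up definition."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q
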