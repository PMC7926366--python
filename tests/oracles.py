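"""Independent oracles used by the test suite.

These deliberately avoid the library's computational paths: likelihoods are
obtained by exhaustive enumeration over ancestral states, BH by the textbook
step-up recursion, TAAS by direct set comparison, and transition matrices by
scipy's matrix exponential.
"""

from __future__ import annotations

import numpy as np

from amphisel.codon_model import (
    SiteClassMixture,
    mixture_scale_factor,
    site_class_assignments,
    transition_matrix,
)
from amphisel.codon_model import PruningEngine  # only for the shared tree index
from amphisel.codons import N_SENSE


def enumeration_loglik(aln, tree, kappa, mixture: SiteClassMixture, pi):
    """Branch-site lnL by exhaustive summation over all ancestral codon
    states at every internal node (no pruning recursion).

    Only feasible for <=4-taxon trees (61^n_internal assignments).
    """
    eng = PruningEngine(aln, tree)  # borrow the indexed tree + leaf states
    idx = eng.index
    internals = [n for n in range(idx.n_nodes) if idx.children[n]]
    if len(internals) > 3:
        raise ValueError("enumeration oracle limited to 3 internal nodes")
    leaves = [n for n in range(idx.n_nodes) if not idx.children[n]]
    n_sites = eng.n_sites
    rate = mixture_scale_factor(kappa, mixture, pi)
    classes = site_class_assignments(mixture)

    # leaf pattern states per site (uncompressed)
    leaf_states = {
        n: eng.states_by_node[n][eng._pattern_of_site] for n in leaves
    }

    total = np.zeros(n_sites)
    for prop, w_bg, w_fg in classes:
        if prop == 0:
            continue
        pmat = {}
        for n in range(idx.n_nodes):
            if idx.parent[n] < 0:
                continue
            w = w_fg if idx.foreground[n] else w_bg
            pmat[n] = transition_matrix(kappa, w, pi, idx.edge_length[n], rate)

        grids = np.indices((N_SENSE,) * len(internals)).reshape(len(internals), -1)
        assign = {node: grids[k] for k, node in enumerate(internals)}
        # probability of the internal assignment itself
        internal_prob = pi[assign[idx.root]].astype(float)
        for n in internals:
            p = idx.parent[n]
            if p < 0:
                continue
            internal_prob = internal_prob * pmat[n][assign[p], assign[n]]
        # per-site leaf factors, chunked over assignments
        f = np.zeros(n_sites)
        n_assign = grids.shape[1]
        for lo in range(0, n_assign, 40000):
            hi = min(lo + 40000, n_assign)
            factor = np.repeat(internal_prob[lo:hi, None], n_sites, axis=1)
            for leaf in leaves:
                par = assign[idx.parent[leaf]][lo:hi]
                factor *= pmat_leaf_entries(pmat[leaf], par, leaf_states[leaf])
            f += factor.sum(axis=0)
        total += prop * f
    with np.errstate(divide="ignore"):
        return float(np.log(total).sum())


def pmat_leaf_entries(pmat: np.ndarray, parent_states: np.ndarray, leaf_states: np.ndarray) -> np.ndarray:
    """P[parent_state, leaf_state] for every (assignment, site) pair;
    missing leaf states (-1) contribute a factor of one."""
    out = np.empty((parent_states.size, leaf_states.size))
    missing = leaf_states < 0
    st = np.where(missing, 0, leaf_states)
    out[:] = pmat[parent_states[:, None], st[None, :]]
    out[:, missing] = 1.0
    return out


def bh_stepup(p_values) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def taas_class_bruteforce(target, background) -> int:
    """Direct four-class TAAS decision by pairwise residue comparison."""
    t = [r for r in target if r not in "-X*" and r]
    b = [r for r in background if r not in "-X*" and r]
    if not t or not b:
        return 0
    for x in t:
        for y in b:
            if x == y:
                return 0
    t_fixed = all(x == t[0] for x in t)
    b_fixed = all(y == b[0] for y in b)
    if t_fixed and b_fixed:
        return 1
    if t_fixed:
        return 2
    if b_fixed:
        return 3
    return 4
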