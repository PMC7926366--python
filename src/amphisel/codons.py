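"""Codon tables for the standard genetic code.

All rate-matrix and likelihood code works on the 61 sense codons of the
standard nuclear code (stop codons are excluded from the state space, as is
conventional for Goldman-Yang style codon models). Tables are derived from
Biopython's standard codon table rather than hard-coded.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons in lexicographic (TCAG) order, as PAML orders them.
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)

N_SENSE = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Amino acid (one-letter) encoded by each sense codon.
CODON_AA: tuple[str, ...] = tuple(_STANDARD.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(x: str, y: str) -> bool:
    """True if the single-nucleotide change x->y is a transition (A<->G, C<->T)."""
    return (x in _PURINES) == (y in _PURINES)


def _pair_tables() -> tuple[np.ndarray, np.ndarray]:
    """Boolean tables over sense-codon pairs that differ at exactly one site.

    Returns (single_step, transition_flag, synonymous_flag) packed as two
    arrays: ``step_type`` with 0 = not a single-nucleotide neighbour,
    1..4 = (syn transversion, syn transition, nonsyn transversion, nonsyn
    transition), and a nucleotide-position array (unused downstream but kept
    for the simulator's diagnostics).
    """
    n = N_SENSE
    step = np.zeros((n, n), dtype=np.int8)
    pos = np.full((n, n), -1, dtype=np.int8)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ts = is_transition(ci[k], cj[k])
            syn = CODON_AA[i] == CODON_AA[j]
            step[i, j] = 1 + (1 if ts else 0) + (0 if syn else 2)
            pos[i, j] = k
    return step, pos


STEP_TYPE, DIFF_POSITION = _pair_tables()

#: Masks used by the rate-matrix builder.
SYN_TRANSVERSION = STEP_TYPE == 1
SYN_TRANSITION = STEP_TYPE == 2
NONSYN_TRANSVERSION = STEP_TYPE == 3
NONSYN_TRANSITION = STEP_TYPE == 4
IS_NONSYN = NONSYN_TRANSVERSION | NONSYN_TRANSITION

#: codon -> (i0, i1, i2) nucleotide indices into NUCLEOTIDES, for F3x4.
CODON_NUC_INDEX = np.array(
    [[NUCLEOTIDES.index(c[k]) for k in range(3)] for c in SENSE_CODONS],
    dtype=np.int64,
)
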