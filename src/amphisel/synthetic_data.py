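"""Synthetic inputs with known ground truth for every pipeline stage.

The default species set mirrors a 12-taxon vertebrate design — four
terrestrial tetrapods (human, mouse, cattle, chicken), coelacanth, an
amphibious mudskipper, and six fully aquatic teleosts — plus elephant shark
as the outgroup for gene-family analyses. Divergence times are
TimeTree-style round numbers in million years; the two water-to-land
foreground branches are the tetrapod ancestor ("Tetrapoda") and the
mudskipper terminal branch.

Codon alignments are simulated exactly under the branch-site model A
generative process (site class drawn from the mixture, root codon from the
equilibrium distribution, branch-wise evolution by matrix-exponential
transition sampling), so the simulator is the generative twin of the
likelihood in :mod:`amphisel.codon_model`. Family count matrices are evolved
by the same birth-death transition law used in :mod:`amphisel.gene_families`.
Every generator is deterministic given its seed and returns a
machine-readable truth table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_model import (
    CodonFrequencies,
    SiteClassMixture,
    _Eigen,
    mixture_scale_factor,
    site_class_assignments,
)
from .codons import SENSE_CODONS, STOP_CODONS
from .gene_families import bd_transition_matrix, default_cmax
from .io_core import CodonAlignment, CodonSequenceSet, LabeledTree, ProteinAlignment

#: 13-taxon time tree (million years), tetrapod ancestor labeled.
DEFAULT_TIME_TREE_NEWICK = (
    "(elephant_shark:465,((coelacanth:413,(chicken:312,(cattle:96,"
    "(human:90,mouse:90):6):216)Tetrapoda:101)Sarcopterygii:17,"
    "(zebrafish:230,((mudskipper:110,glassfish:110):10,((clownfish:95,"
    "easternhappy:95):15,(medaka:104,molly:104):6):10)Percomorpha:110)"
    "Actinopterygii:200)Osteichthyes:35);"
)

TETRAPODS = ["human", "mouse", "cattle", "chicken"]
FOREGROUND_TETRAPOD = "Tetrapoda"
FOREGROUND_MUDSKIPPER = "mudskipper"

#: Default total tree length of the 12-taxon selection tree, in expected
#: substitutions per codon site (vertebrate-scale coding divergence).
DEFAULT_TOTAL_SUBS = 3.0


def default_time_tree() -> LabeledTree:
    """13-taxon time-calibrated tree (with the elephant shark outgroup) used
    by the gene-family analyses."""
    return LabeledTree.from_newick(DEFAULT_TIME_TREE_NEWICK)


def default_selection_tree(
    foreground: set[str] | None = None,
    total_subs: float = DEFAULT_TOTAL_SUBS,
    foreground_factor: float | None = None,
) -> LabeledTree:
    """12-taxon tree in substitution units for branch-site analyses.

    The time tree (outgroup dropped) is rescaled so its total length is
    ``total_subs`` expected substitutions per codon site; relative branch
    lengths follow divergence times. ``foreground`` defaults to both
    water-to-land branches. ``foreground_factor`` optionally multiplies the
    foreground branches after rescaling (used to study site-detection power
    in informative regimes).
    """
    tree = default_time_tree().drop_taxa({"elephant_shark"})
    tree = tree.scaled(total_subs / tree.total_length())
    if foreground is None:
        foreground = {FOREGROUND_TETRAPOD, FOREGROUND_MUDSKIPPER}
    tree = tree.with_foreground(foreground)
    if foreground_factor is not None:
        tree = tree.scaled(1.0, foreground_factor=foreground_factor)
    return tree


@dataclass
class SimulationSpec:
    """Conditions of one synthetic branch-site study."""

    tree: LabeledTree
    mixture: SiteClassMixture
    kappa: float = 2.0
    n_codons: int = 300
    pi: CodonFrequencies | None = None
    seed: int = 0
    #: optional planted per-site classes ('0', '1', '2a', '2b'; '' = draw
    #: from the mixture), e.g. a planted block of foreground-selected sites
    planted_classes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.pi is None:
            self.pi = CodonFrequencies.uniform()
        if self.planted_classes is not None:
            if len(self.planted_classes) != self.n_codons:
                raise ValueError("planted_classes length must equal n_codons")
            bad = set(self.planted_classes) - {"", "0", "1", "2a", "2b"}
            if bad:
                raise ValueError(f"invalid planted classes: {sorted(bad)}")


#: Generator defaults for the site-class mixture: half the sites strongly
#: purifying, 30% neutral, 20% in the foreground classes.
def default_mixture(omega2: float = 1.0) -> SiteClassMixture:
    return SiteClassMixture(p0=0.5, p1=0.3, omega0=0.1, omega2=max(omega2, 1.0))


def _sample_categorical(rng: np.random.Generator, rows: np.ndarray) -> np.ndarray:
    """Sample one index per row of a row-stochastic matrix slice."""
    cum = rows.cumsum(axis=1)
    cum[:, -1] = np.maximum(cum[:, -1], 1.0)
    u = rng.random(rows.shape[0])
    return (cum < u[:, None]).sum(axis=1)


def simulate_codon_alignment(
    spec: SimulationSpec,
) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve a codon alignment under branch-site model A.

    Returns the alignment and a truth table with the drawn site class per
    column (0, 1, 2a='2a', 2b='2b') and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    tindex = spec.tree.to_index()
    pi = spec.pi.pi
    classes = site_class_assignments(spec.mixture)
    props = np.array([p for p, _, _ in classes])
    rate = mixture_scale_factor(spec.kappa, spec.mixture, pi)
    s = spec.n_codons
    site_class = rng.choice(4, size=s, p=props / props.sum())
    if spec.planted_classes is not None:
        label_index = {"0": 0, "1": 1, "2a": 2, "2b": 3}
        for j, lab in enumerate(spec.planted_classes):
            if lab:
                site_class[j] = label_index[lab]

    # per-class transition matrices for every branch
    omegas = sorted({w for _, wb, wf in classes for w in (wb, wf)})
    eig = {w: _Eigen(spec.kappa, w, pi) for w in omegas}
    teff = tindex.edge_length / rate
    pmats = {w: eig[w].transition_matrices(teff) for w in omegas}

    states = np.empty((tindex.n_nodes, s), dtype=np.int64)
    states[tindex.root] = rng.choice(len(pi), size=s, p=pi / pi.sum())
    for node in reversed(tindex.postorder):  # preorder traversal
        for child in tindex.children[node]:
            child_states = np.empty(s, dtype=np.int64)
            for c, (_, w_bg, w_fg) in enumerate(classes):
                w = w_fg if tindex.foreground[child] else w_bg
                sites = np.flatnonzero(site_class == c)
                if sites.size == 0:
                    continue
                rows = pmats[w][child][states[node][sites]]
                child_states[sites] = _sample_categorical(rng, rows)
            states[child] = child_states

    taxa = spec.tree.leaves()
    codon_arr = np.array(SENSE_CODONS)
    mat = np.stack([codon_arr[states[tindex.leaf_of_taxon[t]]] for t in taxa])
    aln = CodonAlignment(taxa=taxa, codons=mat)
    labels = np.array(["0", "1", "2a", "2b"])[site_class]
    truth = pd.DataFrame(
        {
            "column": np.arange(1, s + 1),
            "true_class": labels,
            "foreground_selected": np.isin(labels, ["2a", "2b"]).astype(int),
            "seed": spec.seed,
        }
    )
    return aln, truth


def simulate_gene_battery(
    tree: LabeledTree,
    gene_specs: list[dict],
    seed: int = 0,
) -> tuple[dict[str, CodonAlignment], pd.DataFrame]:
    """Simulate a battery of genes.

    gene_specs: one dict per gene with keys ``gene_id``, ``omega2``,
    ``foreground`` (set of branch ids; empty/None = simulate with omega2
    ineffective), and optional ``n_codons``. Returns alignments keyed by
    gene id plus a per-gene truth table.
    """
    alignments: dict[str, CodonAlignment] = {}
    rows = []
    for k, g in enumerate(gene_specs):
        omega2 = float(g.get("omega2", 1.0))
        fg = g.get("foreground")
        gtree = tree if fg is None else tree.with_foreground(set(fg))
        spec = SimulationSpec(
            tree=gtree,
            mixture=default_mixture(omega2),
            n_codons=int(g.get("n_codons", 300)),
            seed=seed * 100003 + k,
        )
        aln, _ = simulate_codon_alignment(spec)
        gid = g["gene_id"]
        alignments[gid] = aln
        rows.append(
            {
                "gene_id": gid,
                "omega2": omega2,
                "foreground": "+".join(sorted(fg)) if fg else "",
                "n_codons": spec.n_codons,
                "selected": int(omega2 > 1.0 and bool(fg)),
                "seed": spec.seed,
            }
        )
    return alignments, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Defective CDS sets
# ---------------------------------------------------------------------------

_SENSE_NO_STOP = [c for c in SENSE_CODONS]


def make_defective_cds(
    n_valid: int,
    defects: list[str],
    seed: int = 0,
    n_codons: int = 50,
) -> tuple[CodonSequenceSet, pd.DataFrame]:
    """Random CDS set with planted filtering defects.

    Valid genes are in-frame and stop-free (ATG start, sense codons, TAA
    terminal stop). Each entry of ``defects`` ("length_not_multiple_of_3" or
    "internal_stop") plants exactly one labeled defective gene.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    rows = []

    def random_cds() -> str:
        body = rng.choice(_SENSE_NO_STOP, size=n_codons - 2)
        return "ATG" + "".join(body) + "TAA"

    for i in range(n_valid):
        gid = f"gene_valid_{i + 1}"
        records.append((gid, random_cds()))
        rows.append({"gene_id": gid, "defect": ""})
    for i, defect in enumerate(defects):
        gid = f"gene_defect_{i + 1}"
        seq = random_cds()
        if defect == "length_not_multiple_of_3":
            seq = seq + "A" * int(rng.integers(1, 3))
        elif defect == "internal_stop":
            stop = str(rng.choice(sorted(STOP_CODONS)))
            pos = int(rng.integers(1, n_codons - 1)) * 3
            seq = seq[:pos] + stop + seq[pos + 3 :]
        else:
            raise ValueError(f"unknown defect type: {defect}")
        records.append((gid, seq))
        rows.append({"gene_id": gid, "defect": defect})
    order = rng.permutation(len(records))
    records = [records[k] for k in order]
    truth = pd.DataFrame(rows)
    truth["seed"] = seed
    return CodonSequenceSet(records, source="synthetic"), truth


# ---------------------------------------------------------------------------
# Planted TAAS / EAASPS panels
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PlantedColumn:
    """One planted target-exclusive column."""

    column: int  # 1-based
    taas_class: int  # 1..4
    target_fraction: float = 1.0      # conservation of the pattern in the
    background_fraction: float = 1.0  # extended target / background panels


def _fraction_count(frac: float, n: int, what: str) -> int:
    k = frac * n
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"requested {what} fraction {frac} unreachable with panel size {n}"
        )
    return int(round(k))


def plant_taas_panel(
    base: ProteinAlignment,
    target_taxa: list[str],
    planted: list[PlantedColumn],
    n_extended_target: int = 10,
    n_extended_background: int = 20,
    seed: int = 0,
) -> tuple[ProteinAlignment, ProteinAlignment, ProteinAlignment, pd.DataFrame]:
    """Rewrite selected columns of a protein alignment so target and
    background residue sets are disjoint with the requested class, and build
    extended ortholog panels with controlled conservation fractions.

    Returns (core_panel, extended_target_panel, extended_background_panel,
    truth_table).
    """
    cols = [p.column for p in planted]
    if len(set(cols)) != len(cols):
        raise ValueError("planted columns must be disjoint")
    rng = np.random.default_rng(seed)
    core = ProteinAlignment(
        taxa=list(base.taxa), residues=base.residues.copy()
    )
    t_rows = [core.taxa.index(t) for t in target_taxa]
    b_rows = [i for i in range(len(core.taxa)) if i not in t_rows]
    if not t_rows or not b_rows:
        raise ValueError("need non-empty target and background taxon sets")

    n_cols = core.n_cols
    ext_t = np.empty((n_extended_target, n_cols), dtype="<U1")
    ext_b = np.empty((n_extended_background, n_cols), dtype="<U1")
    # unplanted columns follow the core panel (conserved orthologs)
    ext_t[:, :] = core.residues[t_rows[0], :][None, :]
    ext_b[:, :] = core.residues[b_rows[0], :][None, :]

    rows = []
    for p in planted:
        if not 1 <= p.taas_class <= 4:
            raise ValueError("taas_class must be 1..4")
        j = p.column - 1
        n_t = 1 if p.taas_class in (1, 2) else 2
        n_b = 1 if p.taas_class in (1, 3) else 2
        if n_t > len(t_rows) or n_b > len(b_rows):
            raise ValueError("not enough taxa for requested class")
        letters = rng.permutation(list(_AA))
        t_set = list(letters[:n_t])
        b_set = list(letters[n_t : n_t + n_b])
        off_letter = letters[n_t + n_b]  # in neither set
        for k, r in enumerate(t_rows):
            core.residues[r, j] = t_set[k % n_t]
        for k, r in enumerate(b_rows):
            core.residues[r, j] = b_set[k % n_b]

        kt = _fraction_count(p.target_fraction, n_extended_target, "target")
        kb = _fraction_count(p.background_fraction, n_extended_background, "background")
        for k in range(n_extended_target):
            ext_t[k, j] = t_set[k % n_t] if k < kt else b_set[0]
        for k in range(n_extended_background):
            ext_b[k, j] = (b_set[k % n_b] if k % 2 else off_letter) if k < kb \
                else t_set[0]
        rows.append(
            {
                "column": p.column,
                "taas_class": p.taas_class,
                "target_set": "".join(sorted(t_set)),
                "background_set": "".join(sorted(b_set)),
                "target_fraction": p.target_fraction,
                "background_fraction": p.background_fraction,
                "seed": seed,
            }
        )
    ext_target = ProteinAlignment(
        taxa=[f"ext_target_{k + 1}" for k in range(n_extended_target)], residues=ext_t
    )
    ext_background = ProteinAlignment(
        taxa=[f"ext_background_{k + 1}" for k in range(n_extended_background)],
        residues=ext_b,
    )
    return core, ext_target, ext_background, pd.DataFrame(rows)


def random_protein_alignment(
    taxa: list[str], n_cols: int, seed: int = 0, conservation: float = 0.7
) -> ProteinAlignment:
    """Protein alignment where each column is conserved (one residue) with
    probability ``conservation`` and otherwise holds two random residues."""
    rng = np.random.default_rng(seed)
    res = np.empty((len(taxa), n_cols), dtype="<U1")
    aa = np.array(list(_AA))
    for j in range(n_cols):
        if rng.random() < conservation:
            res[:, j] = rng.choice(aa)
        else:
            pair = rng.choice(aa, size=2, replace=False)
            res[:, j] = rng.choice(pair, size=len(taxa))
    return ProteinAlignment(taxa=list(taxa), residues=res)


# ---------------------------------------------------------------------------
# Gene-family count matrices
# ---------------------------------------------------------------------------

@dataclass
class PlantedFamilyEvent:
    """Deterministic size change planted on one branch of one family."""

    family_index: int
    branch_id: str
    factor: float  # <1 contraction, >1 expansion


def simulate_family_matrix(
    tree: LabeledTree,
    lam: float,
    n_families: int,
    root_range: tuple[int, int] = (1, 10),
    planted_events: list[PlantedFamilyEvent] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve a families x species count matrix under the equal-rate
    birth-death process on a time tree.

    Root sizes are uniform on ``root_range``; planted events override the
    sampled child count on the named branch (child = round(parent * factor)).
    Returns (matrix, truth) where truth records root sizes and planted
    events.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    rng = np.random.default_rng(seed)
    planted_events = planted_events or []
    planted_by_branch: dict[str, list[PlantedFamilyEvent]] = {}
    for ev in planted_events:
        planted_by_branch.setdefault(ev.branch_id, []).append(ev)

    tindex = tree.to_index()
    lo, hi = root_range
    roots = rng.integers(lo, hi + 1, size=n_families)
    # generous truncation for simulation transition rows
    cmax = default_cmax(hi) * 2 + 20
    cache: dict[float, np.ndarray] = {}

    states = np.empty((tindex.n_nodes, n_families), dtype=np.int64)
    states[tindex.root] = roots
    for node in reversed(tindex.postorder):
        for child in tindex.children[node]:
            t = float(tindex.edge_length[child])
            if lam == 0.0 or t == 0.0:
                states[child] = states[node]
            else:
                if t not in cache:
                    cache[t] = bd_transition_matrix(lam, t, cmax)
                rows = cache[t][states[node]]
                states[child] = _sample_categorical(rng, rows)
            bid = tindex.branch_ids[child]
            for ev in planted_by_branch.get(bid, []):
                parent_count = states[node][ev.family_index]
                states[child][ev.family_index] = max(
                    int(round(parent_count * ev.factor)), 0
                )

    leaves = tree.leaves()
    fam_ids = [f"fam_{k + 1}" for k in range(n_families)]
    matrix = pd.DataFrame(
        {sp: states[tindex.leaf_of_taxon[sp]] for sp in leaves}, index=fam_ids
    )
    matrix.index.name = "family_id"
    truth_rows = [
        {"family_id": fam_ids[k], "root_size": int(roots[k]), "planted_branch": "",
         "planted_factor": np.nan, "seed": seed}
        for k in range(n_families)
    ]
    for ev in planted_events:
        truth_rows[ev.family_index]["planted_branch"] = ev.branch_id
        truth_rows[ev.family_index]["planted_factor"] = ev.factor
    return matrix, pd.DataFrame(truth_rows)
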