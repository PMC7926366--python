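"""Input handling: CDS sets, codon alignments, labeled species trees, domain tables.

Conventions
-----------
* Alignment columns are 1-based in all user-facing tables; internal arrays are
  0-based.
* Protein-domain intervals are 1-based inclusive on protein-residue
  coordinates (residue 1 = first codon column).
* Foreground branches in Newick are marked with the ``#1`` suffix used by
  branch-site analyses, attached to a leaf name (``mudskipper#1``) or to an
  internal node (``(...)#1`` or ``(...)Tetrapoda#1``).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .codons import CODON_INDEX, STOP_CODONS

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN-")

REASON_LENGTH = "length_not_multiple_of_3"
REASON_INTERNAL_STOP = "internal_stop"
REASON_BAD_CHAR = "invalid_character"


# ---------------------------------------------------------------------------
# CDS sets
# ---------------------------------------------------------------------------

@dataclass
class CodonSequenceSet:
    """Unaligned coding sequences, one per taxon (or one per gene)."""

    records: list[tuple[str, str]]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        ids = [t for t, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids in CodonSequenceSet")
        for tid, seq in self.records:
            bad = set(seq.upper()) - _VALID_CHARS
            if bad:
                raise ValueError(f"{tid}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path: str) -> "CodonSequenceSet":
        recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
        return cls(records=recs, source=str(path))

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for tid, seq in self.records:
                fh.write(f">{tid}\n{seq}\n")


def _has_internal_stop(seq: str) -> bool:
    for k in range(0, len(seq) - 3, 3):
        if seq[k : k + 3] in STOP_CODONS:
            return True
    return False


def filter_cds(
    cds_set: CodonSequenceSet, require_no_internal_stop: bool = True
) -> tuple[CodonSequenceSet, list[tuple[str, str]]]:
    """Drop CDS whose length is not a multiple of 3 (and, by default, those
    with an in-frame stop codon before the final codon).

    Returns the kept set and a list of ``(sequence_id, reason)`` pairs with
    machine-readable reason codes.
    """
    if len(cds_set) == 0:
        logger.warning("filter_cds called on an empty sequence set")
        return CodonSequenceSet([], source=cds_set.source), []
    kept: list[tuple[str, str]] = []
    dropped: list[tuple[str, str]] = []
    for tid, seq in cds_set.records:
        if len(seq) % 3 != 0:
            dropped.append((tid, REASON_LENGTH))
        elif require_no_internal_stop and _has_internal_stop(seq):
            dropped.append((tid, REASON_INTERNAL_STOP))
        else:
            kept.append((tid, seq))
    return CodonSequenceSet(kept, source=cds_set.source), dropped


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame codon alignment: rows are taxa, columns are codons."""

    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_codons) array of 3-character strings

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.codons.ndim != 2:
            raise ValueError("codon matrix must be 2-dimensional")
        if len(self.taxa) != self.codons.shape[0]:
            raise ValueError("taxon count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "CodonAlignment":
        if not records:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            raise ValueError("rows have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("row length not a multiple of 3")
        taxa = [t for t, _ in records]
        mat = np.array(
            [[s[k : k + 3].upper() for k in range(0, length, 3)] for _, s in records],
            dtype="<U3",
        )
        return cls(taxa=taxa, codons=mat)

    @classmethod
    def from_fasta(cls, path: str) -> "CodonAlignment":
        return cls.from_records(
            [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
        )

    def row(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(self.codons[i])

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.taxa):
                fh.write(f">{t}\n{''.join(self.codons[i])}\n")

    def subset_columns(self, keep: np.ndarray) -> "CodonAlignment":
        return CodonAlignment(taxa=list(self.taxa), codons=self.codons[:, keep])

    def to_state_matrix(self) -> np.ndarray:
        """Integer codon states (index into the 61 sense codons); -1 for gap,
        ambiguous or stop codons, which the likelihood marginalizes over."""
        out = np.full(self.codons.shape, -1, dtype=np.int16)
        flat = self.codons.ravel()
        states = np.array([CODON_INDEX.get(c, -1) for c in flat], dtype=np.int16)
        out.ravel()[:] = states
        return out


@dataclass
class TrimPolicy:
    """Codon-column trimming policy.

    drop_gap_columns: remove columns containing any gapped codon.
    drop_ambiguous: remove columns containing any codon with N (or a stop).
    min_conservation: if set, additionally remove columns whose modal codon
    is shared by fewer than this fraction of rows.
    """

    drop_gap_columns: bool = True
    drop_ambiguous: bool = True
    min_conservation: float | None = None


@dataclass
class TrimResult:
    alignment: CodonAlignment
    mask: np.ndarray  # bool, length = input n_codons; True = column retained

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def mask_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.mask.size + 1),
                "retained": self.mask.astype(int),
            }
        )


def trim_codon_columns(
    aln: CodonAlignment, policy: TrimPolicy | None = None
) -> TrimResult:
    """Remove whole codon columns according to ``policy``.

    Raises ValueError("empty_after_trim") when nothing survives, mirroring the
    exclusion of genes with no sequence remaining after trimming.
    """
    policy = policy or TrimPolicy()
    mask = np.ones(aln.n_codons, dtype=bool)
    has_gap = np.char.find(aln.codons, "-") >= 0
    has_n = np.char.find(aln.codons, "N") >= 0
    is_stop = np.isin(aln.codons, sorted(STOP_CODONS))
    if policy.drop_gap_columns:
        mask &= ~has_gap.any(axis=0)
    if policy.drop_ambiguous:
        mask &= ~(has_n | is_stop).any(axis=0)
    if policy.min_conservation is not None:
        for j in np.flatnonzero(mask):
            col = aln.codons[:, j]
            ok = ~(has_gap[:, j] | has_n[:, j])
            if not ok.any():
                mask[j] = False
                continue
            _, counts = np.unique(col[ok], return_counts=True)
            if counts.max() / aln.n_taxa < policy.min_conservation:
                mask[j] = False
    if not mask.any():
        raise ValueError("empty_after_trim")
    return TrimResult(alignment=aln.subset_columns(mask), mask=mask)


@dataclass
class ProteinAlignment:
    """Protein alignment; one residue per codon column of its source."""

    taxa: list[str]
    residues: np.ndarray  # (n_taxa, n_cols) of single characters

    @property
    def n_cols(self) -> int:
        return self.residues.shape[1]

    def column(self, pos1: int) -> dict[str, str]:
        """Residues at 1-based column ``pos1`` keyed by taxon."""
        return {t: self.residues[i, pos1 - 1] for i, t in enumerate(self.taxa)}

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "ProteinAlignment":
        lengths = {len(s) for _, s in records}
        if len(lengths) != 1:
            raise ValueError("rows have unequal lengths")
        return cls(
            taxa=[t for t, _ in records],
            residues=np.array([list(s.upper()) for _, s in records], dtype="<U1"),
        )

    @classmethod
    def from_fasta(cls, path: str) -> "ProteinAlignment":
        return cls.from_records(
            [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
        )

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.taxa):
                fh.write(f">{t}\n{''.join(self.residues[i])}\n")


def translate_codon(codon: str, lenient: bool = False, final: bool = False) -> str:
    if codon == "---":
        return "-"
    if "-" in codon or "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        if final or lenient:
            return "*"
        raise ValueError(f"in-frame stop codon {codon} in non-final column")
    return str(Seq(codon).translate())


def translate_alignment(aln: CodonAlignment, lenient: bool = False) -> ProteinAlignment:
    """Translate every codon column: gap codon -> '-', N-containing -> 'X',
    internal stop -> error (or '*' in lenient mode)."""
    n = aln.n_codons
    out = np.empty(aln.codons.shape, dtype="<U1")
    for i in range(aln.n_taxa):
        for j in range(n):
            out[i, j] = translate_codon(
                aln.codons[i, j], lenient=lenient, final=(j == n - 1)
            )
    return ProteinAlignment(taxa=list(aln.taxa), residues=out)


# ---------------------------------------------------------------------------
# Labeled trees
# ---------------------------------------------------------------------------

_FG_SUFFIX = "#1"


@dataclass
class TreeIndex:
    """Array form of a rooted tree for the pruning engines.

    Nodes are indexed 0..n_nodes-1 with the root last in ``postorder``.
    ``edge_length[v]`` and ``foreground[v]`` describe the branch above v.
    """

    n_nodes: int
    postorder: list[int]
    children: list[list[int]]
    parent: np.ndarray
    edge_length: np.ndarray
    foreground: np.ndarray
    leaf_of_taxon: dict[str, int]
    branch_ids: list[str]
    root: int


class LabeledTree:
    """Species tree with branch lengths and foreground-branch flags.

    Branch ids: a branch is named by the node below it — the taxon label for
    terminal branches, the internal node's label when the Newick provides
    one, otherwise the sorted '+'-joined leaf set of its clade.
    """

    def __init__(self, tree: dendropy.Tree, foreground: set[str] | None = None):
        self._tree = tree
        self.foreground: set[str] = set(foreground or set())
        known = set(self.branch_ids())
        unknown = self.foreground - known
        if unknown:
            raise ValueError(f"foreground flags on unknown branches: {sorted(unknown)}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick_text: str) -> "LabeledTree":
        try:
            tree = dendropy.Tree.get(
                data=newick_text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed newick: {exc}") from exc
        # canonicalize: merge unifurcations so clade-based branch ids are
        # unique (lengths are summed by dendropy)
        tree.suppress_unifurcations()
        fg: set[str] = set()
        for node in tree.preorder_node_iter():
            if node.taxon is not None and node.taxon.label.endswith(_FG_SUFFIX):
                node.taxon.label = node.taxon.label[: -len(_FG_SUFFIX)]
                fg.add(_branch_id_of(node))
            elif node.label is not None and node.label.endswith(_FG_SUFFIX):
                node.label = node.label[: -len(_FG_SUFFIX)] or None
                fg.add(_branch_id_of(node))
        return cls(tree, foreground=fg)

    @classmethod
    def from_file(cls, path: str) -> "LabeledTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic accessors ----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaves(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def branch_ids(self) -> list[str]:
        return [
            _branch_id_of(n)
            for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        ]

    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        )

    # -- transforms ---------------------------------------------------------

    def copy(self) -> "LabeledTree":
        return LabeledTree.from_newick(self.to_newick())

    def scaled(self, factor: float, foreground_factor: float | None = None) -> "LabeledTree":
        """Multiply all branch lengths by ``factor`` (foreground branches by
        ``foreground_factor`` instead, when given)."""
        out = self.copy()
        for node in out._tree.preorder_node_iter():
            if node.parent_node is None or node.edge.length is None:
                continue
            f = factor
            if foreground_factor is not None and _branch_id_of(node) in out.foreground:
                f = foreground_factor
            node.edge.length = node.edge.length * f
        return out

    def with_foreground(self, branches: set[str]) -> "LabeledTree":
        out = self.copy()
        out.foreground = set()
        known = set(out.branch_ids())
        unknown = set(branches) - known
        if unknown:
            raise ValueError(f"unknown foreground branches: {sorted(unknown)}")
        out.foreground = set(branches)
        return out

    def drop_taxa(self, taxa: set[str]) -> "LabeledTree":
        out = self.copy()
        keep = [t for t in out.leaves() if t not in taxa]
        out._tree.retain_taxa_with_labels(keep)
        # suppress unifurcations created by pruning
        out._tree.suppress_unifurcations()
        out.foreground &= set(out.branch_ids())
        return out

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        buf = io.StringIO()

        def write_node(node: dendropy.Node) -> None:
            if node.is_leaf():
                buf.write(node.taxon.label)
            else:
                buf.write("(")
                for k, ch in enumerate(node.child_nodes()):
                    if k:
                        buf.write(",")
                    write_node(ch)
                buf.write(")")
                if node.label:
                    buf.write(node.label)
            if node.parent_node is not None:
                if _branch_id_of(node) in self.foreground:
                    buf.write(_FG_SUFFIX)
                if node.edge.length is not None:
                    buf.write(":" + format(node.edge.length, "g"))

        write_node(self._tree.seed_node)
        buf.write(";")
        return buf.getvalue()

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- array form ---------------------------------------------------------

    def to_index(self, missing_ok: bool = False) -> TreeIndex:
        nodes = list(self._tree.preorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n, dtype=float)
        fg = np.zeros(n, dtype=bool)
        children: list[list[int]] = [[] for _ in range(n)]
        leaf_of_taxon: dict[str, int] = {}
        branch_ids: list[str] = [""] * n
        for i, node in enumerate(nodes):
            branch_ids[i] = _branch_id_of(node)
            if node.parent_node is not None:
                p = idx[id(node.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = node.edge.length or 0.0
                fg[i] = branch_ids[i] in self.foreground
            if node.is_leaf():
                leaf_of_taxon[node.taxon.label] = i
        postorder = [idx[id(x)] for x in self._tree.postorder_node_iter()]
        return TreeIndex(
            n_nodes=n,
            postorder=postorder,
            children=children,
            parent=parent,
            edge_length=lengths,
            foreground=fg,
            leaf_of_taxon=leaf_of_taxon,
            branch_ids=branch_ids,
            root=idx[id(self._tree.seed_node)],
        )


def _branch_id_of(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def parse_labeled_tree(newick_text: str) -> LabeledTree:
    """Parse a Newick string carrying optional ``#1`` foreground markers."""
    return LabeledTree.from_newick(newick_text)


# ---------------------------------------------------------------------------
# Domain tables
# ---------------------------------------------------------------------------

DOMAIN_COLUMNS = ["protein_id", "domain_name", "start", "end", "source"]


def read_domain_table(path: str) -> pd.DataFrame:
    """Read a protein-domain interval table (TSV; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_name": str})
    missing = set(DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    return validate_domain_table(df)


def validate_domain_table(df: pd.DataFrame) -> pd.DataFrame:
    if ((df["start"] < 1) | (df["end"] < df["start"])).any():
        raise ValueError("domain intervals must satisfy 1 <= start <= end")
    return df


# ---------------------------------------------------------------------------
# Family count matrices (I/O only; the model lives in gene_families)
# ---------------------------------------------------------------------------

def read_family_counts(path: str) -> pd.DataFrame:
    """Families x species gene-count matrix from TSV (first column = family id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("gene-family counts must be non-negative")
    return df.astype(int)


def write_family_counts(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="family_id")
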