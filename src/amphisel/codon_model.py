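"""Branch-site codon model A: rate matrix, likelihood, ML fitting, BEB.

The model follows the classical branch-site test of positive selection:
four site classes with nonsynonymous/synonymous rate ratios

====== ============ ============
class  background   foreground
====== ============ ============
0      omega0 < 1   omega0
1      1            1
2a     omega0       omega2
2b     1            omega2
====== ============ ============

with proportions (p0, p1, p2a, p2b), p2a = (1-p0-p1) p0/(p0+p1) and
p2b = (1-p0-p1) p1/(p0+p1). "Foreground" branches are those flagged in the
species tree; the alternative model estimates omega2 >= 1 while the null
fixes omega2 = 1, giving a likelihood-ratio test with one constrained
parameter.

Substitution process: Goldman-Yang style 61-state Markov generator with
transition/transversion ratio kappa and F3x4 equilibrium frequencies.
Generators are normalized so that one unit of branch length equals one
expected substitution per codon site averaged over site classes on
background branches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

from .codons import (
    CODON_NUC_INDEX,
    N_SENSE,
    NONSYN_TRANSITION,
    NONSYN_TRANSVERSION,
    SYN_TRANSITION,
    SYN_TRANSVERSION,
)
from .io_core import CodonAlignment, LabeledTree, TreeIndex

logger = logging.getLogger(__name__)

#: Default number of optimization starts per model fit (deterministic
#: starts -- null-seeded for the alternative -- plus random restarts).
DEFAULT_N_STARTS = 2

OMEGA0_BOUNDS = (1e-6, 0.9999)
OMEGA2_BOUNDS = (1.0, 999.0)
KAPPA_BOUNDS = (0.05, 50.0)
SCALE_BOUNDS = (1e-3, 100.0)


# ---------------------------------------------------------------------------
# Frequencies and generator
# ---------------------------------------------------------------------------

@dataclass
class CodonFrequencies:
    """Equilibrium frequencies over the 61 sense codons."""

    pi: np.ndarray
    scheme: str = "f3x4"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_SENSE,):
            raise ValueError(f"pi must have length {N_SENSE}")
        if (self.pi < 0).any():
            raise ValueError("negative codon frequency")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "CodonFrequencies":
        return cls(pi=np.full(N_SENSE, 1.0 / N_SENSE), scheme="uniform")


def estimate_f3x4(aln: CodonAlignment, floor: float = 1e-6) -> CodonFrequencies:
    """F3x4 codon frequencies: product of position-specific nucleotide
    frequencies, stop codons excluded, renormalized over the 61 sense codons.

    Zero-frequency codons are floored at ``floor`` (then renormalized) so the
    generator stays irreducible; pass ``floor=0`` for the raw estimate.
    """
    counts = np.zeros((3, 4), dtype=float)  # positions x TCAG
    nuc_order = "TCAG"
    flat = aln.codons.ravel()
    for codon in flat:
        for k, ch in enumerate(codon):
            idx = nuc_order.find(ch)
            if idx >= 0:
                counts[k, idx] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a codon position has no unambiguous nucleotides")
    freq = counts / counts.sum(axis=1, keepdims=True)
    pi = (
        freq[0, CODON_NUC_INDEX[:, 0]]
        * freq[1, CODON_NUC_INDEX[:, 1]]
        * freq[2, CODON_NUC_INDEX[:, 2]]
    )
    total = pi.sum()
    if total == 0:
        raise ValueError("degenerate F3x4 estimate")
    pi = pi / total
    if floor > 0 and (pi == 0).any():
        pi = np.maximum(pi, floor)
        pi = pi / pi.sum()
    return CodonFrequencies(pi=pi, scheme="f3x4")


def build_rate_matrix(
    kappa: float, omega: float, pi: CodonFrequencies | np.ndarray
) -> np.ndarray:
    """Unscaled Goldman-Yang generator over the 61 sense codons.

    q(i->j) = pi_j * {1, kappa, omega, omega*kappa} for synonymous
    transversions/transitions and nonsynonymous transversions/transitions;
    zero when codons differ at more than one position; diagonal = -row sum.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    p = pi.pi if isinstance(pi, CodonFrequencies) else np.asarray(pi, dtype=float)
    if p.shape != (N_SENSE,) or (p < 0).any():
        raise ValueError("invalid codon frequencies")
    mult = (
        SYN_TRANSVERSION * 1.0
        + SYN_TRANSITION * kappa
        + NONSYN_TRANSVERSION * omega
        + NONSYN_TRANSITION * (omega * kappa)
    )
    q = mult * p[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def mean_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per unit time under generator ``q`` at
    stationarity."""
    return float(-(pi * np.diag(q)).sum())


# ---------------------------------------------------------------------------
# Site-class mixture
# ---------------------------------------------------------------------------

@dataclass
class SiteClassMixture:
    """Proportions and omegas of the four branch-site classes."""

    p0: float
    p1: float
    omega0: float
    omega2: float

    def __post_init__(self) -> None:
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("need p0, p1 >= 0 and p0 + p1 <= 1")
        if not (0 < self.omega0 < 1):
            raise ValueError("omega0 must lie in (0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")

    @property
    def p2a(self) -> float:
        if self.p0 + self.p1 == 0:
            raise ValueError("p0 + p1 = 0: class 2 proportions undefined")
        return (1 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        if self.p0 + self.p1 == 0:
            raise ValueError("p0 + p1 = 0: class 2 proportions undefined")
        return (1 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])


def site_class_assignments(
    mixture: SiteClassMixture,
) -> list[tuple[float, float, float]]:
    """(proportion, omega_background, omega_foreground) for the four classes."""
    w0, w2 = mixture.omega0, mixture.omega2
    return [
        (mixture.p0, w0, w0),
        (mixture.p1, 1.0, 1.0),
        (mixture.p2a, w0, w2),
        (mixture.p2b, 1.0, w2),
    ]


def mixture_scale_factor(
    kappa: float, mixture: SiteClassMixture, pi: np.ndarray
) -> float:
    """Class-weighted mean substitution rate on background branches; dividing
    the generator by this makes branch lengths expected substitutions per
    codon site."""
    r0 = mean_rate(build_rate_matrix(kappa, mixture.omega0, pi), pi)
    r1 = mean_rate(build_rate_matrix(kappa, 1.0, pi), pi)
    props = mixture.proportions()
    return float((props[0] + props[2]) * r0 + (props[1] + props[3]) * r1)


@dataclass
class CodonModelParams:
    """Full parameter set of one branch-site fit."""

    kappa: float
    mixture: SiteClassMixture
    pi: CodonFrequencies
    branch_lengths: np.ndarray | None = None  # per TreeIndex node; None = tree's own
    tree_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.branch_lengths is not None and (np.asarray(self.branch_lengths) < 0).any():
            raise ValueError("negative branch length")


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------

class _Eigen:
    """Eigendecomposition of the reversible generator for fast exp(Q t)."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        q = build_rate_matrix(kappa, omega, pi)
        self.rate = mean_rate(q, pi)
        sq = np.sqrt(np.maximum(pi, 1e-300))
        b = q * (sq[:, None] / sq[None, :])
        b = 0.5 * (b + b.T)
        try:
            lam, v = scipy.linalg.eigh(b)
            self.lam = lam
            self.A = v / sq[:, None]
            self.Ainv = v.T * sq[None, :]
            self._q = None
        except scipy.linalg.LinAlgError:  # pragma: no cover - defensive
            self.lam = None
            self._q = q

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """exp(Q t) for each t in ``ts`` (Q unscaled here; scale ts upstream)."""
        ts = np.asarray(ts, dtype=float)
        if self.lam is None:  # pragma: no cover - expm fallback
            return np.array([scipy.linalg.expm(self._q * t) for t in ts])
        e = np.exp(np.multiply.outer(ts, self.lam))  # (B, 61)
        p = np.matmul(self.A[None, :, :] * e[:, None, :], self.Ainv)
        np.clip(p, 0.0, None, out=p)
        return p


def transition_matrix(
    kappa: float, omega: float, pi: np.ndarray, t: float, rate_scale: float = 1.0
) -> np.ndarray:
    """exp(Q t / rate_scale) for a single branch (convenience/testing API)."""
    eig = _Eigen(kappa, omega, pi)
    return eig.transition_matrices(np.array([t / rate_scale]))[0]


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Felsenstein pruning over a codon alignment and an indexed tree.

    Built once per gene; evaluates per-site log-likelihoods for arbitrary
    (omega_background, omega_foreground) class definitions, which is the
    kernel shared by ML fitting and BEB.
    """

    def __init__(self, aln: CodonAlignment, tree: LabeledTree):
        leaves = set(tree.leaves())
        missing = set(aln.taxa) - leaves
        if missing:
            raise ValueError(f"alignment taxa absent from tree: {sorted(missing)}")
        extra = leaves - set(aln.taxa)
        if extra:
            tree = tree.drop_taxa(extra)
        self.tree = tree
        self.index: TreeIndex = tree.to_index()
        states = aln.to_state_matrix()
        self.n_sites = states.shape[1]
        # site-pattern compression: identical columns are computed once
        patterns, self._pattern_of_site = np.unique(
            states, axis=1, return_inverse=True
        )
        self._pattern_of_site = self._pattern_of_site.ravel()
        self.n_patterns = patterns.shape[1]
        self.states_by_node: dict[int, np.ndarray] = {}
        for taxon, node in self.index.leaf_of_taxon.items():
            row = aln.taxa.index(taxon)
            self.states_by_node[node] = patterns[row].astype(np.int64)
        self._eigen_cache: dict[tuple, _Eigen] = {}

    def _eigen(self, kappa: float, omega: float, pi: np.ndarray) -> _Eigen:
        key = (round(float(kappa), 12), round(float(omega), 12), id(pi))
        eig = self._eigen_cache.get(key)
        if eig is None:
            if len(self._eigen_cache) > 128:
                self._eigen_cache.clear()
            eig = _Eigen(kappa, omega, pi)
            self._eigen_cache[key] = eig
        return eig

    # -- core kernel --------------------------------------------------------

    def class_site_loglik(
        self,
        pi: np.ndarray,
        kappa: float,
        class_defs: list[tuple[float, float]],
        rate_scale: float,
        branch_lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """log site likelihoods, shape (n_classes, n_sites).

        class_defs: (omega_background, omega_foreground) per class.
        rate_scale: generator normalization (mixture-weighted mean rate).
        branch_lengths: per-node lengths overriding the tree's own.
        """
        idx = self.index
        lengths = idx.edge_length if branch_lengths is None else branch_lengths
        teff = np.asarray(lengths, dtype=float) / rate_scale

        # compute each omega's transition matrices only on the branches that
        # use it (foreground omegas are needed on foreground branches only)
        need: dict[float, np.ndarray] = {}
        has_branch = idx.parent >= 0
        fg = idx.foreground & has_branch
        bg = (~idx.foreground) & has_branch
        for w_bg, w_fg in class_defs:
            need[w_bg] = need.get(w_bg, np.zeros(idx.n_nodes, bool)) | bg
            need[w_fg] = need.get(w_fg, np.zeros(idx.n_nodes, bool)) | fg
        pmats: dict[float, np.ndarray] = {}
        for w, mask in need.items():
            # transposed P padded with a trailing "missing" row of ones, so a
            # leaf state of -1 (gap/ambiguous) indexes an all-ones partial
            full = np.empty((idx.n_nodes, N_SENSE + 1, N_SENSE))
            nodes = np.flatnonzero(mask)
            p = self._eigen(kappa, w, pi).transition_matrices(teff[nodes])
            full[nodes, :N_SENSE] = np.swapaxes(p, 1, 2)
            full[nodes, N_SENSE] = 1.0
            pmats[w] = full

        # per-node rescaling is skipped on small trees (float64 headroom);
        # underflow triggers the slow rescaled path
        rescale = idx.n_nodes > 40
        out = np.empty((len(class_defs), self.n_patterns))
        for c, (w_bg, w_fg) in enumerate(class_defs):
            lf = self._prune_one(pi, pmats[w_bg], pmats[w_fg], rescale)
            if not rescale and not np.isfinite(lf).all():
                lf = self._prune_one(pi, pmats[w_bg], pmats[w_fg], True)
            out[c] = lf
        return out[:, self._pattern_of_site]  # expand patterns to sites

    def _prune_one(
        self, pi: np.ndarray, pt_bg: np.ndarray, pt_fg: np.ndarray, rescale: bool
    ) -> np.ndarray:
        idx = self.index
        partials: dict[int, np.ndarray] = {}
        logsc: dict[int, np.ndarray] = {}
        for node in idx.postorder:
            if not idx.children[node]:
                continue
            part = None
            scale_acc = None
            for child in idx.children[node]:
                pt = pt_fg[child] if idx.foreground[child] else pt_bg[child]
                st = self.states_by_node.get(child)
                if st is not None:
                    contrib = pt[st]  # (s, 61); -1 hits the missing row
                else:
                    contrib = partials.pop(child) @ pt[:N_SENSE]
                    sc = logsc.pop(child)
                    if sc is not None:
                        scale_acc = sc if scale_acc is None else scale_acc + sc
                if part is None:
                    part = contrib  # fresh array from gather/matmul
                else:
                    part *= contrib
            if rescale:
                m = part.max(axis=1)
                bad = m <= 0
                if bad.any():
                    sites = np.flatnonzero(bad) + 1
                    logger.warning("zero partial likelihood at site(s) %s", sites[:5])
                    m = np.where(bad, 1.0, m)
                part /= m[:, None]
                sc = np.where(m > 0, np.log(m), -np.inf)
                scale_acc = sc if scale_acc is None else scale_acc + sc
            partials[node] = part
            logsc[node] = scale_acc
        root = idx.root
        f = partials[root] @ pi
        with np.errstate(divide="ignore"):
            lf = np.log(f)
        return lf if logsc[root] is None else lf + logsc[root]

    # -- mixture likelihood --------------------------------------------------

    def mixture_loglik(
        self,
        pi: np.ndarray,
        kappa: float,
        mixture: SiteClassMixture,
        branch_lengths: np.ndarray | None = None,
        return_site_class: bool = False,
    ):
        classes = site_class_assignments(mixture)
        rate = mixture_scale_factor(kappa, mixture, pi)
        logf = self.class_site_loglik(
            pi, kappa, [(wb, wf) for _, wb, wf in classes], rate, branch_lengths
        )
        props = np.array([p for p, _, _ in classes])
        # stable mixture: sum_c p_c exp(logf_c)
        m = logf.max(axis=0)
        shifted = np.exp(logf - m[None, :])
        mix = (props[:, None] * shifted).sum(axis=0)
        site_ll = m + np.log(np.maximum(mix, 1e-300))
        neg = mix <= 0
        if neg.any():
            site_ll[neg] = -np.inf
        if return_site_class:
            post = props[:, None] * shifted
            post /= np.maximum(post.sum(axis=0, keepdims=True), 1e-300)
            return site_ll, post.T  # (n_sites, 4)
        return site_ll


def log_likelihood(
    aln: CodonAlignment, tree: LabeledTree, params: CodonModelParams
) -> float:
    """Branch-site model A log-likelihood of a codon alignment."""
    engine = PruningEngine(aln, tree)
    lengths = params.branch_lengths
    if lengths is None and params.tree_scale != 1.0:
        lengths = engine.index.edge_length * params.tree_scale
    site_ll = engine.mixture_loglik(
        params.pi.pi, params.kappa, params.mixture, branch_lengths=lengths
    )
    return float(site_ll.sum())


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

@dataclass
class BranchSiteFit:
    """Result of one gene x one model ML fit."""

    gene_id: str
    model: str  # "alternative" | "null"
    lnL: float
    params: CodonModelParams
    converged: bool
    n_evaluations: int
    n_starts: int
    seed: int
    message: str = ""
    site_class_posteriors: np.ndarray | None = None  # (n_sites, 4), at the MLE

    @property
    def omega2(self) -> float:
        return self.params.mixture.omega2


def _unpack(x: np.ndarray, alternative: bool) -> tuple[float, SiteClassMixture, float]:
    kappa = float(np.exp(x[0]))
    s = 1.0 / (1.0 + np.exp(-x[1]))
    f = 1.0 / (1.0 + np.exp(-x[2]))
    p0, p1 = s * f, s * (1 - f)
    w0 = float(np.exp(x[3]))
    scale = float(np.exp(x[4]))
    w2 = float(np.exp(x[5])) if alternative else 1.0
    mixture = SiteClassMixture(p0=p0, p1=p1, omega0=min(w0, OMEGA0_BOUNDS[1]),
                               omega2=max(w2, 1.0))
    return kappa, mixture, scale


def _pack(kappa, p0, p1, w0, scale, w2=None) -> np.ndarray:
    s = min(max(p0 + p1, 1e-6), 1 - 1e-6)
    f = min(max(p0 / s, 1e-6), 1 - 1e-6)

    def logit(u):
        return float(np.log(u / (1 - u)))

    x = [np.log(kappa), logit(s), logit(f), np.log(w0), np.log(scale)]
    if w2 is not None:
        x.append(np.log(max(w2, 1.0 + 1e-9)))
    return np.array(x)


def _bounds(alternative: bool) -> list[tuple[float, float]]:
    b = [
        (np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1])),
        (-8.0, 8.0),
        (-8.0, 8.0),
        (np.log(OMEGA0_BOUNDS[0]), np.log(OMEGA0_BOUNDS[1])),
        (np.log(SCALE_BOUNDS[0]), np.log(SCALE_BOUNDS[1])),
    ]
    if alternative:
        b.append((0.0, np.log(OMEGA2_BOUNDS[1])))
    return b


def fit_branch_site(
    aln: CodonAlignment,
    tree: LabeledTree,
    mode: str = "alternative",
    gene_id: str = "",
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    null_fit: "BranchSiteFit | None" = None,
    max_fun: int = 500,
    tol: float = 1e-8,
) -> BranchSiteFit:
    """Maximum-likelihood branch-site fit (alternative: omega2 free in
    [1, 999]; null: omega2 fixed at 1).

    Free parameters: kappa, (p0, p1), omega0, omega2 (alternative only) and a
    per-gene tree-scale factor multiplying the input tree's relative branch
    lengths (expected substitutions per codon site). Multi-start bounded
    quasi-Newton optimization; the alternative is additionally seeded at the
    null optimum so nested-model likelihood ordering holds by construction.
    """
    if mode not in ("alternative", "null"):
        raise ValueError("mode must be 'alternative' or 'null'")
    alternative = mode == "alternative"
    engine = PruningEngine(aln, tree)
    pi = estimate_f3x4(aln)
    rng = np.random.default_rng(seed)
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            kappa, mixture, scale = _unpack(x, alternative)
        except ValueError:
            return 1e12
        lengths = engine.index.edge_length * scale
        site_ll = engine.mixture_loglik(pi.pi, kappa, mixture, branch_lengths=lengths)
        val = float(site_ll.sum())
        if not np.isfinite(val):
            return 1e12
        return -val

    starts: list[np.ndarray] = []
    base = _pack(2.0, 0.45, 0.30, 0.1, 1.0, 2.0 if alternative else None)
    if alternative and null_fit is not None:
        # null-seeded start guarantees the nested-model lnL ordering; the
        # independent base start matters because the null optimum can be
        # degenerate (p0 + p1 near a boundary), leaving omega2 with a flat
        # or misleading local gradient
        m = null_fit.params.mixture
        starts.append(
            _pack(null_fit.params.kappa, m.p0, m.p1, m.omega0,
                  null_fit.params.tree_scale, 1.000001)
        )
        starts.append(base)
        starts.append(
            _pack(null_fit.params.kappa, 0.45, 0.30, m.omega0,
                  null_fit.params.tree_scale, 6.0)
        )
    else:
        starts.append(base)
    while len(starts) < max(n_starts, 1):
        jitter = rng.normal(0.0, 0.5, size=base.size)
        starts.append(np.clip(base + jitter,
                              [b[0] for b in _bounds(alternative)],
                              [b[1] for b in _bounds(alternative)]))

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=_bounds(alternative),
            options={"maxfun": max_fun, "ftol": tol, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    converged = bool(best is not None and np.isfinite(best.fun))
    kappa, mixture, scale = _unpack(best.x, alternative)
    lnL = -float(best.fun)

    # Guarantee lnL_alt >= lnL_null on the same gene.
    if alternative and null_fit is not None and lnL < null_fit.lnL:
        m = null_fit.params.mixture
        kappa, scale = null_fit.params.kappa, null_fit.params.tree_scale
        mixture = SiteClassMixture(p0=m.p0, p1=m.p1, omega0=m.omega0, omega2=1.0)
        lnL = null_fit.lnL

    lengths = engine.index.edge_length * scale
    site_ll, post = engine.mixture_loglik(
        pi.pi, kappa, mixture, branch_lengths=lengths, return_site_class=True
    )
    params = CodonModelParams(
        kappa=kappa, mixture=mixture, pi=pi, branch_lengths=lengths, tree_scale=scale
    )
    return BranchSiteFit(
        gene_id=gene_id,
        model=mode,
        lnL=lnL,
        params=params,
        converged=converged,
        n_evaluations=n_eval,
        n_starts=len(starts),
        seed=seed,
        message=str(getattr(best, "message", "")),
        site_class_posteriors=post,
    )


def fit_gene(
    aln: CodonAlignment,
    tree: LabeledTree,
    gene_id: str = "",
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    max_fun: int = 500,
) -> tuple[BranchSiteFit, BranchSiteFit]:
    """Fit null then alternative (seeded from the null optimum); returns
    (null_fit, alternative_fit) with lnL_alt >= lnL_null guaranteed."""
    null = fit_branch_site(
        aln, tree, mode="null", gene_id=gene_id, n_starts=n_starts,
        seed=seed, max_fun=max_fun,
    )
    alt = fit_branch_site(
        aln, tree, mode="alternative", gene_id=gene_id, n_starts=n_starts,
        seed=seed + 1, null_fit=null, max_fun=max_fun,
    )
    return null, alt


# ---------------------------------------------------------------------------
# Bayes empirical Bayes site posteriors
# ---------------------------------------------------------------------------

@dataclass
class BEBResult:
    """Per-site posterior over the four site classes, BEB-averaged."""

    class_posteriors: np.ndarray  # (n_sites, 4)

    @property
    def selected(self) -> np.ndarray:
        """Posterior probability of foreground selection (class 2a + 2b)."""
        return self.class_posteriors[:, 2] + self.class_posteriors[:, 3]


def beb_site_posteriors(
    aln: CodonAlignment,
    tree: LabeledTree,
    fit: BranchSiteFit,
    grid_size: int = 10,
    omega2_max: float = 11.0,
) -> BEBResult:
    """Bayes empirical Bayes posterior of foreground selection per site.

    The mixture parameters (p0, p1, omega0, omega2) are integrated over a
    uniform discrete prior grid (``grid_size`` points per dimension; the
    (p0, p1) pair over the triangular simplex grid), weighting each grid
    point by its data likelihood. Branch lengths, kappa, and codon
    frequencies are held at the ML estimates of the alternative fit, and the
    generator normalization is held at the MLE's scaling so site-class
    likelihoods factorize over the grid.
    """
    if fit.model != "alternative":
        raise ValueError("BEB requires an alternative-model fit")
    if not fit.converged:
        raise ValueError("BEB requires a converged fit")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")

    engine = PruningEngine(aln, tree)
    pi = fit.params.pi.pi
    kappa = fit.params.kappa
    lengths = fit.params.branch_lengths
    d = grid_size
    w0_grid = (np.arange(d) + 0.5) / d
    w2_grid = 1.0 + (np.arange(d) + 0.5) / d * (omega2_max - 1.0)
    rate = mixture_scale_factor(kappa, fit.params.mixture, pi)

    # site-class log-likelihood components on the grid
    class_defs = []
    class_defs.extend((w0, w0) for w0 in w0_grid)          # class 0, per w0
    class_defs.append((1.0, 1.0))                          # class 1
    class_defs.extend((w0, w2) for w0 in w0_grid for w2 in w2_grid)  # 2a
    class_defs.extend((1.0, w2) for w2 in w2_grid)         # 2b
    logf = engine.class_site_loglik(pi, kappa, class_defs, rate, lengths)
    s = engine.n_sites
    lf0 = logf[:d]                            # (d, S)
    lf1 = logf[d]                             # (S,)
    lf2a = logf[d + 1 : d + 1 + d * d].reshape(d, d, s)  # (w0, w2, S)
    lf2b = logf[d + 1 + d * d :]              # (d, S)

    # triangular (p0, p1) grid
    pairs = [
        ((i + 0.5) / d, (j + 0.5) / d)
        for i in range(d)
        for j in range(d)
        if (i + 0.5) / d + (j + 0.5) / d <= 1.0
    ]
    props = np.array(
        [SiteClassMixture(p0, p1, 0.5, 2.0).proportions() for p0, p1 in pairs]
    )  # (M, 4)
    m_pairs = len(pairs)

    # mixture log-likelihood per (pair, w0, w2, site), computed stably
    shift = np.maximum.reduce(
        [lf0.max(axis=0), lf1, lf2a.max(axis=(0, 1)), lf2b.max(axis=0)]
    )  # (S,)
    e0 = np.exp(lf0 - shift)        # (d, S)
    e1 = np.exp(lf1 - shift)        # (S,)
    e2a = np.exp(lf2a - shift)      # (d, d, S)
    e2b = np.exp(lf2b - shift)      # (d, S)

    # f_mix[m, i, j, s]
    f_mix = (
        props[:, 0, None, None, None] * e0[None, :, None, :]
        + props[:, 1, None, None, None] * e1[None, None, None, :]
        + props[:, 2, None, None, None] * e2a[None, :, :, :]
        + props[:, 3, None, None, None] * e2b[None, None, :, :]
    )
    f_mix = np.maximum(f_mix, 1e-300)
    log_marg = np.log(f_mix).sum(axis=3)  # (M, d, d)
    log_marg -= log_marg.max()
    w = np.exp(log_marg)
    w /= w.sum()

    post = np.zeros((s, 4))
    num0 = props[:, 0, None, None, None] * e0[None, :, None, :]
    num1 = props[:, 1, None, None, None] * e1[None, None, None, :] * np.ones_like(f_mix)
    num2a = props[:, 2, None, None, None] * e2a[None, :, :, :] * np.ones_like(f_mix)
    num2b = props[:, 3, None, None, None] * e2b[None, None, :, :] * np.ones_like(f_mix)
    wt = w[:, :, :, None]
    post[:, 0] = (wt * num0 / f_mix).sum(axis=(0, 1, 2))
    post[:, 1] = (wt * num1 / f_mix).sum(axis=(0, 1, 2))
    post[:, 2] = (wt * num2a / f_mix).sum(axis=(0, 1, 2))
    post[:, 3] = (wt * num2b / f_mix).sum(axis=(0, 1, 2))
    post /= np.maximum(post.sum(axis=1, keepdims=True), 1e-300)
    return BEBResult(class_posteriors=post)
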