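"""Birth-death gene-family evolution: likelihood, rate estimation, rapid
expansion/contraction calls, and convergent-contraction screening.

Model: each gene copy in a family is independently gained or lost at the
same rate ``lambda`` per gene per million years along a time-calibrated
species tree (equal birth and death rates). The probability that a family of
size ``s`` in a parent has size ``c`` in a child after time ``t`` has the
classical closed form in alpha = lambda*t / (1 + lambda*t); size 0 is
absorbing. A single global lambda is estimated by maximum likelihood over
all families; per-family p-values are Monte-Carlo tail probabilities of the
family likelihood under the fitted model, and per-branch change calls come
from most-probable ancestral counts (max-product dynamic programming).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import comb

from .io_core import LabeledTree, TreeIndex

logger = logging.getLogger(__name__)


@dataclass
class BirthDeathParams:
    """Equal-rate birth-death parameters (lambda per gene per million years)."""

    lambda_: float
    lnL: float | None = None
    at_lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")

    def alpha(self, t: float) -> float:
        """alpha = lambda*t / (1 + lambda*t), the per-copy loss probability."""
        return self.lambda_ * t / (1.0 + self.lambda_ * t)


@dataclass
class FamilyTestResult:
    family_id: str
    lnL: float
    p_value: float
    branch_calls: dict[str, str]       # branch id -> expansion|contraction|none
    ancestral_counts: dict[str, int]   # branch id (node below) -> inferred count


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def bd_transition_prob(s: int, c: int, lam: float, t: float) -> float:
    """P(child count = c | parent count = s) under the equal-rate
    birth-death process over time t."""
    if s < 0 or c < 0 or lam < 0 or t < 0:
        raise ValueError("s, c, lambda and t must be non-negative")
    if s == 0:
        return 1.0 if c == 0 else 0.0
    alpha = lam * t / (1.0 + lam * t)
    if alpha == 0.0:
        return 1.0 if c == s else 0.0
    j = np.arange(0, min(s, c) + 1)
    terms = (
        comb(s, j)
        * comb(s + c - j - 1, s - 1)
        * alpha ** (s + c - 2 * j)
        * (1.0 - 2.0 * alpha) ** j
    )
    return float(max(terms.sum(), 0.0))


def bd_transition_matrix(lam: float, t: float, cmax: int) -> np.ndarray:
    """(cmax+1) x (cmax+1) matrix P[s, c] of bd_transition_prob values."""
    n = cmax + 1
    alpha = lam * t / (1.0 + lam * t) if t > 0 else 0.0
    if alpha == 0.0:
        return np.eye(n)
    s_idx = np.arange(n)[:, None]
    c_idx = np.arange(n)[None, :]
    maxn = 2 * cmax + 2
    # binomial lookup: T[m, k] = C(m, k) (zero when m < k)
    table = comb(np.arange(maxn + 1)[:, None], np.arange(n)[None, :])
    beta = 1.0 - 2.0 * alpha
    apow = alpha ** np.arange(2 * cmax + 1)
    p = np.zeros((n, n))
    s_minus_1 = np.broadcast_to(np.maximum(s_idx - 1, 0), (n, n))
    for j in range(n):
        valid = (s_idx >= max(j, 1)) & (c_idx >= j)
        if not valid.any():
            break
        m = np.clip(s_idx + c_idx - j - 1, 0, maxn)
        term = (
            table[s_idx, j]
            * table[m, s_minus_1]
            * apow[s_idx + c_idx - 2 * j]
            * beta**j
        )
        p += np.where(valid, term, 0.0)
    np.maximum(p, 0.0, out=p)
    p[0] = 0.0
    p[0, 0] = 1.0
    return p


def bd_generator(lam: float, cmax: int) -> np.ndarray:
    """Truncated generator of the equal-rate birth-death process (size 0
    absorbing); oracle companion of the closed-form transition matrix."""
    g = np.zeros((cmax + 1, cmax + 1))
    for n in range(1, cmax + 1):
        if n < cmax:
            g[n, n + 1] = n * lam
        g[n, n - 1] = n * lam
        g[n, n] = -g[n].sum()
    return g


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def default_cmax(max_count: int) -> int:
    return int(max_count) * 2 + 10


def uniform_root_prior(cmax: int, lo: int = 1, hi: int | None = None) -> np.ndarray:
    """Uniform prior over root sizes lo..hi (default 1..cmax: conditional on
    a non-extinct family at the root)."""
    hi = cmax if hi is None else min(hi, cmax)
    prior = np.zeros(cmax + 1)
    prior[lo : hi + 1] = 1.0
    return prior / prior.sum()


def _branch_matrices(
    tindex: TreeIndex, lam: float, cmax: int
) -> dict[int, np.ndarray]:
    mats: dict[int, np.ndarray] = {}
    cache: dict[float, np.ndarray] = {}
    for node in range(tindex.n_nodes):
        if tindex.parent[node] < 0:
            continue
        t = float(tindex.edge_length[node])
        if t not in cache:
            cache[t] = bd_transition_matrix(lam, t, cmax)
        mats[node] = cache[t]
    return mats


def _batch_family_loglik(
    counts: np.ndarray,  # (n_families, n_species) aligned to species order
    species: list[str],
    tindex: TreeIndex,
    lam: float,
    cmax: int,
    root_prior: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of each family under a single lambda (vectorized
    pruning over count states 0..cmax)."""
    if counts.max(initial=0) > cmax:
        raise ValueError("truncation bound below the maximum observed count")
    mats = _branch_matrices(tindex, lam, cmax)
    nf = counts.shape[0]
    leaf_vec: dict[int, np.ndarray] = {}
    for k, sp in enumerate(species):
        node = tindex.leaf_of_taxon[sp]
        v = np.zeros((nf, cmax + 1))
        v[np.arange(nf), counts[:, k]] = 1.0
        leaf_vec[node] = v
    partials: dict[int, np.ndarray] = {}
    logsc: dict[int, np.ndarray] = {}
    for node in tindex.postorder:
        if not tindex.children[node]:
            continue
        part = np.ones((nf, cmax + 1))
        acc = np.zeros(nf)
        for child in tindex.children[node]:
            v = leaf_vec.get(child)
            if v is None:
                v = partials.pop(child)
                acc += logsc.pop(child)
            part *= v @ mats[child].T
        m = np.maximum(part.max(axis=1), 1e-300)
        part /= m[:, None]
        partials[node] = part
        logsc[node] = acc + np.log(m)
    root = tindex.root
    f = partials[root] @ root_prior
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(f, 1e-300)) + logsc[root]


def family_log_likelihood(
    counts: "pd.Series | dict[str, int]",
    tree: LabeledTree,
    params: BirthDeathParams,
    cmax: int | None = None,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of a single family's leaf counts."""
    if isinstance(counts, dict):
        counts = pd.Series(counts)
    species = list(counts.index)
    missing = set(tree.leaves()) - set(species)
    if missing:
        raise ValueError(f"counts missing for species: {sorted(missing)}")
    arr = counts.to_numpy(dtype=int)[None, :]
    if cmax is None:
        cmax = default_cmax(arr.max())
    if root_prior is None:
        root_prior = uniform_root_prior(cmax)
    tindex = tree.to_index()
    return float(
        _batch_family_loglik(arr, species, tindex, params.lambda_, cmax, root_prior)[0]
    )


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

def estimate_lambda(
    matrix: pd.DataFrame,
    tree: LabeledTree,
    cmax: int | None = None,
    root_prior_range: tuple[int, int] | None = None,
    bounds: tuple[float, float] = (1e-8, 0.5),
) -> BirthDeathParams:
    """Single-rate ML estimate of lambda over all families.

    matrix: families x species count DataFrame; columns must equal the
    tree's leaf set. ``root_prior_range`` optionally restricts the uniform
    root prior to lo..hi (defaults to 1..cmax).
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 families to estimate lambda")
    species = list(matrix.columns)
    if set(species) != set(tree.leaves()):
        raise ValueError("matrix species do not match tree leaves")
    counts = matrix.to_numpy(dtype=int)
    if cmax is None:
        cmax = default_cmax(counts.max())
    lo, hi = root_prior_range if root_prior_range else (1, cmax)
    root_prior = uniform_root_prior(cmax, lo, hi)
    tindex = tree.to_index()

    def nll(log_lam: float) -> float:
        lam = float(np.exp(log_lam))
        return -float(
            _batch_family_loglik(counts, species, tindex, lam, cmax, root_prior).sum()
        )

    res = minimize_scalar(
        nll,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},  # <0.1% relative precision on lambda
    )
    lam_hat = float(np.exp(res.x))
    at_bound = lam_hat <= bounds[0] * 1.5
    if at_bound:
        logger.warning("lambda estimate at lower bound (no-change data?)")
    return BirthDeathParams(lambda_=lam_hat, lnL=-float(res.fun), at_lower_bound=at_bound)


# ---------------------------------------------------------------------------
# Monte-Carlo p-values
# ---------------------------------------------------------------------------

def simulate_null_families(
    tree: LabeledTree,
    params: BirthDeathParams,
    n_sim: int,
    seed: int,
    cmax: int,
    root_prior: np.ndarray,
) -> np.ndarray:
    """Simulate leaf-count rows for n_sim families under the fitted model,
    root sizes drawn from ``root_prior``. Returns (n_sim, n_leaves) counts in
    the order of ``tree.leaves()``."""
    rng = np.random.default_rng(seed)
    tindex = tree.to_index()
    mats = _branch_matrices(tindex, params.lambda_, cmax)
    states = np.empty((tindex.n_nodes, n_sim), dtype=np.int64)
    states[tindex.root] = rng.choice(cmax + 1, size=n_sim, p=root_prior)
    for node in reversed(tindex.postorder):  # preorder
        for child in tindex.children[node]:
            p = mats[child]
            cum = p.cumsum(axis=1)
            u = rng.random(n_sim)
            rows = cum[states[node]]
            states[child] = (rows < u[:, None]).sum(axis=1)
    leaves = tree.leaves()
    return np.stack([states[tindex.leaf_of_taxon[sp]] for sp in leaves], axis=1)


def family_pvalues(
    matrix: pd.DataFrame,
    tree: LabeledTree,
    params: BirthDeathParams,
    n_sim: int = 1000,
    seed: int = 0,
    cmax: int | None = None,
    root_prior_range: tuple[int, int] | None = None,
) -> pd.Series:
    """Monte-Carlo p-value per family: the fraction of families simulated
    under the fitted single-rate model whose log-likelihood is <= the
    observed family's, with an add-one correction (p >= 1/(n_sim+1))."""
    if n_sim < 100:
        logger.warning("n_sim=%d is small; p-values will be coarse", n_sim)
    species = list(matrix.columns)
    counts = matrix.to_numpy(dtype=int)
    if cmax is None:
        cmax = default_cmax(counts.max())
    lo, hi = root_prior_range if root_prior_range else (1, cmax)
    root_prior = uniform_root_prior(cmax, lo, hi)
    tindex = tree.to_index()
    sim = simulate_null_families(tree, params, n_sim, seed, cmax, root_prior)
    sim_cmax = max(cmax, default_cmax(sim.max()))
    if sim_cmax > cmax:
        root_prior = np.pad(root_prior, (0, sim_cmax - cmax))
        cmax = sim_cmax
    leaves = tree.leaves()
    sim_ll = _batch_family_loglik(sim, leaves, tindex, params.lambda_, cmax, root_prior)
    obs = matrix[leaves].to_numpy(dtype=int)
    obs_ll = _batch_family_loglik(obs, leaves, tindex, params.lambda_, cmax, root_prior)
    p = (1.0 + (sim_ll[None, :] <= obs_ll[:, None]).sum(axis=1)) / (n_sim + 1.0)
    return pd.Series(p, index=matrix.index, name="p_value")


def family_pvalue(
    counts: "pd.Series | dict[str, int]",
    tree: LabeledTree,
    params: BirthDeathParams,
    n_sim: int = 1000,
    seed: int = 0,
    cmax: int | None = None,
    root_prior_range: tuple[int, int] | None = None,
) -> float:
    """Monte-Carlo p-value for a single family (see family_pvalues)."""
    if isinstance(counts, dict):
        counts = pd.Series(counts)
    df = pd.DataFrame([counts])
    return float(
        family_pvalues(
            df, tree, params, n_sim=n_sim, seed=seed, cmax=cmax,
            root_prior_range=root_prior_range,
        ).iloc[0]
    )


# ---------------------------------------------------------------------------
# Ancestral counts and branch calls
# ---------------------------------------------------------------------------

def branch_changes(
    counts: "pd.Series | dict[str, int]",
    tree: LabeledTree,
    params: BirthDeathParams,
    cmax: int | None = None,
    root_prior_range: tuple[int, int] | None = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """Most-probable ancestral counts (max-product DP over count states) and
    per-branch calls: expansion if child > parent, contraction if child <
    parent, none on ties.

    Returns (branch_calls, counts_by_branch_id) where counts include leaves
    and internal nodes keyed by the branch id of the node below each branch
    (the root is keyed by its clade id as well).
    """
    if isinstance(counts, dict):
        counts = pd.Series(counts)
    arr = counts
    if cmax is None:
        cmax = default_cmax(int(arr.max()))
    lo, hi = root_prior_range if root_prior_range else (1, cmax)
    root_prior = uniform_root_prior(cmax, lo, hi)
    tindex = tree.to_index()
    logmats = _log_branch_matrices(tindex, params.lambda_, cmax)
    return _viterbi_calls(arr, tindex, logmats, root_prior, cmax)


def _log_branch_matrices(
    tindex: TreeIndex, lam: float, cmax: int
) -> dict[int, np.ndarray]:
    mats = _branch_matrices(tindex, lam, cmax)
    with np.errstate(divide="ignore"):
        return {k: np.log(np.maximum(v, 1e-300)) for k, v in mats.items()}


def _viterbi_calls(
    arr: pd.Series,
    tindex: TreeIndex,
    logmats: dict[int, np.ndarray],
    root_prior: np.ndarray,
    cmax: int,
) -> tuple[dict[str, str], dict[str, int]]:
    up: dict[int, np.ndarray] = {}
    ptr: dict[int, np.ndarray] = {}
    for node in tindex.postorder:
        if not tindex.children[node]:
            taxon = tindex.branch_ids[node]
            v = np.full(cmax + 1, -np.inf)
            v[int(arr[taxon])] = 0.0
            up[node] = v
            continue
        total = np.zeros(cmax + 1)
        for child in tindex.children[node]:
            scores = logmats[child] + up[child][None, :]  # (parent, child)
            ptr[child] = scores.argmax(axis=1)
            total += scores.max(axis=1)
        up[node] = total
    root = tindex.root
    with np.errstate(divide="ignore"):
        root_scores = up[root] + np.log(np.maximum(root_prior, 1e-300))
    assign = {root: int(root_scores.argmax())}
    for node in reversed(tindex.postorder):
        for child in tindex.children[node]:
            if tindex.children[child]:
                assign[child] = int(ptr[child][assign[node]])
            else:
                assign[child] = int(arr[tindex.branch_ids[child]])

    calls: dict[str, str] = {}
    counts_out: dict[str, int] = {}
    for node in range(tindex.n_nodes):
        bid = tindex.branch_ids[node]
        counts_out[bid] = assign[node]
        p = tindex.parent[node]
        if p < 0:
            continue
        delta = assign[node] - assign[p]
        calls[bid] = "expansion" if delta > 0 else "contraction" if delta < 0 else "none"
    return calls, counts_out


# ---------------------------------------------------------------------------
# Whole-matrix analysis, convergence, summaries
# ---------------------------------------------------------------------------

def analyze_families(
    matrix: pd.DataFrame,
    tree: LabeledTree,
    n_sim: int = 1000,
    seed: int = 0,
    root_prior_range: tuple[int, int] | None = None,
    params: BirthDeathParams | None = None,
) -> tuple[BirthDeathParams, list[FamilyTestResult]]:
    """Estimate lambda (unless given), compute per-family p-values and
    branch calls for every family."""
    cmax = default_cmax(int(matrix.to_numpy().max()))
    if params is None:
        params = estimate_lambda(
            matrix, tree, cmax=cmax, root_prior_range=root_prior_range
        )
    pvals = family_pvalues(
        matrix, tree, params, n_sim=n_sim, seed=seed, cmax=cmax,
        root_prior_range=root_prior_range,
    )
    leaves = tree.leaves()
    tindex = tree.to_index()
    lo, hi = root_prior_range if root_prior_range else (1, cmax)
    root_prior = uniform_root_prior(cmax, lo, hi)
    lls = _batch_family_loglik(
        matrix[leaves].to_numpy(dtype=int), leaves, tindex, params.lambda_, cmax,
        root_prior,
    )
    logmats = _log_branch_matrices(tindex, params.lambda_, cmax)
    results = []
    for k, (fam, row) in enumerate(matrix.iterrows()):
        calls, anc = _viterbi_calls(row, tindex, logmats, root_prior, cmax)
        results.append(
            FamilyTestResult(
                family_id=str(fam),
                lnL=float(lls[k]),
                p_value=float(pvals.iloc[k]),
                branch_calls=calls,
                ancestral_counts=anc,
            )
        )
    return params, results


def convergent_contractions(
    results: list[FamilyTestResult],
    branch_a: str,
    branch_b: str,
    p_threshold: float = 0.05,
) -> set[str]:
    """Families rapidly evolving (p < threshold) and contracted on both of
    the two named branches."""
    if results:
        known = set(results[0].branch_calls)
        for b in (branch_a, branch_b):
            if b not in known:
                raise ValueError(f"unknown branch id: {b}")
    return {
        r.family_id
        for r in results
        if r.p_value < p_threshold
        and r.branch_calls.get(branch_a) == "contraction"
        and r.branch_calls.get(branch_b) == "contraction"
    }


def rapid_branch_summary(
    results: list[FamilyTestResult], p_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-branch counts of rapidly expanded / contracted families."""
    rows = {}
    for r in results:
        if r.p_value >= p_threshold:
            continue
        for branch, call in r.branch_calls.items():
            if call == "none":
                continue
            rows.setdefault(branch, {"expansion": 0, "contraction": 0})
            rows[branch][call] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return df.sort_index()


def group_count_summary(
    matrix: pd.DataFrame,
    family_subset: list[str],
    species_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-species gene totals over a family subset, with per-group means.

    Returns a DataFrame indexed by species with columns total and group, plus
    a group-mean column broadcast per species.
    """
    for g, members in species_groups.items():
        if not members:
            raise ValueError(f"empty species group: {g}")
    sub = matrix.loc[family_subset]
    totals = sub.sum(axis=0)
    rows = []
    for g, members in species_groups.items():
        vals = totals[members]
        for sp in members:
            rows.append({"species": sp, "group": g, "total": int(totals[sp]),
                         "group_mean": float(vals.mean())})
    return pd.DataFrame(rows).set_index("species")


def results_table(results: list[FamilyTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"family_id": r.family_id, "lnL": r.lnL, "p_value": r.p_value}
        for b, call in sorted(r.branch_calls.items()):
            row[f"call:{b}"] = call
        rows.append(row)
    return pd.DataFrame(rows)
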