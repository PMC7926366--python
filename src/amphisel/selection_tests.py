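"""Likelihood-ratio tests, FDR correction, and PSG partitioning.

A gene is called positively selected (PSG) under a foreground design when
the branch-site alternative beats the null (2*deltaL > 0), the foreground
ratio estimate exceeds one (omega2_hat > 1), and the BH-adjusted p-value is
below the FDR threshold (default 0.1). Genes are then partitioned into
lineage-specific sets and a "union" set: union = called in the combined
two-foreground design, or called independently in both single-foreground
designs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .codon_model import BranchSiteFit

logger = logging.getLogger(__name__)

MODELS = ("tetrapod", "mudskipper", "tetrapod_and_mudskipper")

DEFAULT_FDR = 0.1


@dataclass
class LRTResult:
    """Per-gene likelihood-ratio test under one foreground design."""

    gene_id: str
    model: str
    two_delta_L: float  # recorded unclamped
    p_value: float
    omega2_hat: float
    q_value: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass
class PSGPartition:
    """Disjoint PSG sets from the three foreground designs."""

    tetrapod_specific: set[str]
    mudskipper_specific: set[str]
    union: set[str]

    def __post_init__(self) -> None:
        sets = [self.tetrapod_specific, self.mudskipper_specific, self.union]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("partition sets must be pairwise disjoint")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "set": name}
            for name, s in (
                ("tetrapod_specific", self.tetrapod_specific),
                ("mudskipper_specific", self.mudskipper_specific),
                ("union", self.union),
            )
            for g in sorted(s)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "set"])


def lrt(lnL_null: float, lnL_alt: float, df: int = 1) -> tuple[float, float]:
    """2(lnL_alt - lnL_null) and its chi-square upper-tail p-value.

    A negative statistic (optimizer artifact) is reported as-is with p = 1.
    """
    if np.isnan(lnL_null) or np.isnan(lnL_alt):
        raise ValueError("NaN log-likelihood")
    two_delta = 2.0 * (lnL_alt - lnL_null)
    if two_delta < 0:
        warnings.warn(
            f"negative LRT statistic ({two_delta:.4g}); alternative fit did "
            "not reach the null optimum",
            stacklevel=2,
        )
    p = float(chi2.sf(max(two_delta, 0.0), df))
    return float(two_delta), p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_psg(
    result: LRTResult,
    fit: BranchSiteFit | None = None,
    fdr_threshold: float = DEFAULT_FDR,
) -> bool:
    """PSG call: q < threshold AND 2*deltaL > 0 AND omega2_hat > 1.

    Returns False (with a log message) for unconverged fits.
    """
    if np.isnan(result.q_value):
        raise ValueError("q_value not computed; run bh_adjust over the battery first")
    if fit is not None and not fit.converged:
        logger.info("gene %s: unconverged fit, not called", result.gene_id)
        return False
    if not result.converged:
        logger.info("gene %s: unconverged fit, not called", result.gene_id)
        return False
    return (
        result.q_value < fdr_threshold
        and result.two_delta_L > 0.0
        and result.omega2_hat > 1.0
    )


def adjust_battery(results: list[LRTResult]) -> list[LRTResult]:
    """Fill q-values within one model battery (BH across its genes)."""
    if not results:
        return results
    models = {r.model for r in results}
    if len(models) > 1:
        raise ValueError("adjust_battery expects a single model's results")
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def partition_psgs(calls: dict[str, dict[str, bool]]) -> PSGPartition:
    """Partition genes given per-model PSG calls.

    calls: gene_id -> {model name -> called} for the three designs. Genes
    missing any model's call are excluded with a warning.
    """
    tet, mud, union = set(), set(), set()
    for gene, by_model in calls.items():
        missing = set(MODELS) - set(by_model)
        if missing:
            logger.warning("gene %s missing results for %s; excluded", gene, missing)
            continue
        t = by_model["tetrapod"]
        m = by_model["mudskipper"]
        tm = by_model["tetrapod_and_mudskipper"]
        if tm or (t and m):
            union.add(gene)
        elif t:
            tet.add(gene)
        elif m:
            mud.add(gene)
    return PSGPartition(
        tetrapod_specific=tet, mudskipper_specific=mud, union=union
    )


def results_table(results: list[LRTResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "model": r.model,
                "two_delta_L": r.two_delta_L,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "omega2_hat": r.omega2_hat,
                "converged": int(r.converged),
            }
            for r in results
        ]
    )
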