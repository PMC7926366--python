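"""Shared fixtures. The expensive simulation batteries are session-scoped so
unit tests and acceptance tests measure the same computations once."""

from __future__ import annotations

import subprocess
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from amphisel.codon_model import beb_site_posteriors, fit_gene
from amphisel.gene_families import (
    branch_changes,
    estimate_lambda,
    family_pvalues,
)
from amphisel.selection_tests import LRTResult, adjust_battery, lrt
from amphisel.synthetic_data import (
    FOREGROUND_MUDSKIPPER,
    FOREGROUND_TETRAPOD,
    PlantedFamilyEvent,
    SimulationSpec,
    default_mixture,
    default_selection_tree,
    default_time_tree,
    simulate_codon_alignment,
    simulate_family_matrix,
)


@pytest.fixture(scope="session")
def selection_tree():
    """12-taxon substitution-scale tree, both water-to-land branches
    foreground."""
    return default_selection_tree()


@pytest.fixture(scope="session")
def time_tree():
    return default_time_tree()


# ---------------------------------------------------------------------------
# Battery A: null calibration (100 genes, omega2 = 1, 200 codons)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def null_battery(selection_tree):
    """LRT results for 100 genes simulated under the null."""
    results = []
    for k in range(100):
        spec = SimulationSpec(
            tree=selection_tree,
            mixture=default_mixture(1.0),
            n_codons=200,
            seed=10_000 + k,
        )
        aln, _ = simulate_codon_alignment(spec)
        null, alt = fit_gene(aln, selection_tree, gene_id=f"null{k}", seed=k)
        two_delta, p = lrt(null.lnL, alt.lnL)
        results.append(
            {"two_delta_L": two_delta, "p": p, "null": null, "alt": alt}
        )
    return results


# ---------------------------------------------------------------------------
# Battery B: power / parameter recovery (20 genes, omega2 = 4, 500 codons)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def power_battery(selection_tree):
    """Alternative-model recovery on 20 genes simulated with omega2 = 4 on
    both foreground branches."""
    battery = []
    fits = []
    for k in range(20):
        spec = SimulationSpec(
            tree=selection_tree,
            mixture=default_mixture(4.0),
            n_codons=500,
            seed=20_000 + k,
        )
        aln, _ = simulate_codon_alignment(spec)
        null, alt = fit_gene(aln, selection_tree, gene_id=f"pow{k}", seed=k)
        two_delta, p = lrt(null.lnL, alt.lnL)
        battery.append(
            LRTResult(
                gene_id=f"pow{k}",
                model="tetrapod_and_mudskipper",
                two_delta_L=two_delta,
                p_value=p,
                omega2_hat=alt.omega2,
            )
        )
        fits.append((null, alt))
    adjust_battery(battery)
    return {"results": battery, "fits": fits}


# ---------------------------------------------------------------------------
# Battery C: BEB site recovery (planted class-2a block) and null sites
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def beb_battery():
    """Pooled BEB posteriors from genes carrying a planted block of
    foreground-selected (class 2a) sites at omega2 = 8, plus null genes.

    Foreground branches are lengthened (factor 2.5, ~3 expected
    substitutions per site for the selected class) so nearly every planted
    site carries substitutions on both foreground branches — the regime in
    which single-site detection is informative.
    """
    tree = default_selection_tree(foreground_factor=2.5)
    n = 600
    block = ["" for _ in range(100)] + ["2a"] * 300 + ["" for _ in range(200)]
    planted_post, planted_truth = [], []
    null_post = []
    for k in range(3):
        spec = SimulationSpec(
            tree=tree, mixture=default_mixture(8.0), n_codons=n,
            seed=30_000 + k, planted_classes=block,
        )
        aln, truth = simulate_codon_alignment(spec)
        _, alt = fit_gene(aln, tree, gene_id=f"beb{k}", seed=k)
        beb = beb_site_posteriors(aln, tree, alt)
        mask = np.array([bool(c) for c in block])
        planted_post.append(beb.selected[mask])
        planted_truth.append(truth.loc[mask, "true_class"].to_numpy())
    for k in range(3):
        spec = SimulationSpec(
            tree=tree, mixture=default_mixture(1.0), n_codons=n, seed=31_000 + k
        )
        aln, _ = simulate_codon_alignment(spec)
        _, alt = fit_gene(aln, tree, gene_id=f"bebnull{k}", seed=50 + k)
        beb = beb_site_posteriors(aln, tree, alt)
        null_post.append(beb.selected)
    return {
        "planted": np.concatenate(planted_post),
        "null": np.concatenate(null_post),
    }


# ---------------------------------------------------------------------------
# Battery D: birth-death recovery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def family_recovery(time_tree):
    """Lambda recovery at 500 families plus 20 planted-contraction
    replicates (10-fold loss on the mudskipper branch, small lambda)."""
    true_lambda = 0.002
    matrix, _ = simulate_family_matrix(
        time_tree, true_lambda, n_families=500, root_range=(1, 10), seed=40_000
    )
    params = estimate_lambda(matrix, time_tree, root_prior_range=(1, 10))

    replicates = []
    for r in range(20):
        ev = [PlantedFamilyEvent(0, FOREGROUND_MUDSKIPPER, 0.1)]
        mat, _ = simulate_family_matrix(
            time_tree, 0.0005, n_families=60, root_range=(8, 12),
            planted_events=ev, seed=41_000 + r,
        )
        p_hat = estimate_lambda(mat, time_tree, root_prior_range=(8, 12))
        pv = family_pvalues(
            mat, time_tree, p_hat, n_sim=1000, seed=r, root_prior_range=(8, 12)
        )
        calls, _ = branch_changes(
            mat.iloc[0], time_tree, p_hat, root_prior_range=(8, 12)
        )
        replicates.append(
            {
                "planted_p": float(pv.iloc[0]),
                "planted_call": calls[FOREGROUND_MUDSKIPPER],
            }
        )
    return {
        "true_lambda": true_lambda,
        "lambda_hat": params.lambda_,
        "replicates": replicates,
    }


# ---------------------------------------------------------------------------
# Battery E: end-to-end pipeline runs (simulate once, run twice)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """Full CLI round trip: one synthetic study, selection and family
    pipelines each run twice into separate directories."""
    import pandas as pd
    import yaml

    root = tmp_path_factory.mktemp("e2e")
    study = root / "study"
    cmd = [
        sys.executable, "-m", "amphisel.cli", "simulate",
        "--out", str(study), "--seed", "7",
    ]
    subprocess.run(cmd, check=True, capture_output=True)

    config = {
        "alignments_dir": str(study / "alignments"),
        "tree": str(study / "tree.nwk"),
        "family_counts": str(study / "family_counts.tsv"),
        "time_tree": str(study / "time_tree.nwk"),
        "seed": 7,
        "beb_grid": 5,
        "root_prior_range": [1, 10],
    }
    cfg_path = root / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config))

    outs = {}
    for name in ("run1", "run2"):
        outdir = root / name
        subprocess.run(
            [sys.executable, "-m", "amphisel.cli", "selection",
             "--config", str(cfg_path), "--out", str(outdir)],
            check=True, capture_output=True,
        )
        subprocess.run(
            [sys.executable, "-m", "amphisel.cli", "families",
             "--config", str(cfg_path), "--out", str(outdir)],
            check=True, capture_output=True,
        )
        subprocess.run(
            [sys.executable, "-m", "amphisel.cli", "report",
             "--out", str(outdir)],
            check=True, capture_output=True,
        )
        outs[name] = outdir
    truth = pd.read_csv(study / "gene_truth.tsv", sep="\t")
    return {"study": study, "truth": truth, **outs}
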