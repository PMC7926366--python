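"""End-to-end pipelines: selection (filter → trim → three branch-site fits →
LRT/FDR → PSG partition → TAAS/EAASPS scan) and gene families (lambda →
p-values → branch calls → convergent contractions → group summaries).

Both pipelines are deterministic given the config seed: per-gene optimizer
seeds are derived from the gene id, all outputs are written with fixed
formatting, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_model import beb_site_posteriors, fit_gene
from .gene_families import (
    analyze_families,
    convergent_contractions,
    group_count_summary,
    rapid_branch_summary,
    results_table as family_results_table,
)
from .io_core import (
    CodonAlignment,
    LabeledTree,
    ProteinAlignment,
    TrimPolicy,
    read_domain_table,
    read_family_counts,
    translate_alignment,
    trim_codon_columns,
)
from .selection_tests import (
    LRTResult,
    MODELS,
    adjust_battery,
    call_psg,
    lrt,
    partition_psgs,
    results_table as lrt_results_table,
)
from .taas import records_table, scan_gene

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class InputError(ValueError):
    """Invalid or missing pipeline input (CLI exit code 1)."""


@dataclass
class PipelineConfig:
    """Declarative configuration shared by the pipeline subcommands."""

    # selection inputs
    alignments_dir: str | None = None
    tree: str | None = None
    foreground_tetrapod: str = "Tetrapoda"
    foreground_mudskipper: str = "mudskipper"
    tetrapod_taxa: list[str] = field(
        default_factory=lambda: ["human", "mouse", "cattle", "chicken"]
    )
    extended_target_dir: str | None = None
    extended_background_dir: str | None = None
    domains: str | None = None
    # family inputs
    family_counts: str | None = None
    time_tree: str | None = None
    species_groups: dict[str, list[str]] = field(default_factory=dict)
    # thresholds
    fdr: float = 0.1
    pss_cutoff: float = 0.95
    eaasps_threshold: float = 0.9
    family_p: float = 0.05
    # knobs
    seed: int = 0
    beb_grid: int = 10
    n_starts: int = 2
    n_sim: int = 1000
    root_prior_range: list[int] | None = None
    min_conservation: float | None = None

    def __post_init__(self) -> None:
        for name in ("fdr", "pss_cutoff", "eaasps_threshold", "family_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"threshold {name}={v} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise InputError(f"missing_input: config key '{name}' is required")
            if isinstance(value, str) and not Path(value).exists():
                raise InputError(f"missing_input: {name} path not found: {value}")


def _gene_seed(base_seed: int, gene_id: str) -> int:
    return (base_seed * 1000003 + zlib.crc32(gene_id.encode())) % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Selection pipeline
# ---------------------------------------------------------------------------

def design_foreground(config: PipelineConfig, model: str) -> set[str]:
    if model == "tetrapod":
        return {config.foreground_tetrapod}
    if model == "mudskipper":
        return {config.foreground_mudskipper}
    if model == "tetrapod_and_mudskipper":
        return {config.foreground_tetrapod, config.foreground_mudskipper}
    raise ValueError(f"unknown model: {model}")


def design_targets(config: PipelineConfig, model: str) -> list[str]:
    """Target species of the TAAS comparison corresponding to each design."""
    if model == "tetrapod":
        return list(config.tetrapod_taxa)
    if model == "mudskipper":
        return [config.foreground_mudskipper]
    if model == "tetrapod_and_mudskipper":
        return list(config.tetrapod_taxa) + [config.foreground_mudskipper]
    raise ValueError(f"unknown model: {model}")


def run_selection_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run the full positive-selection pipeline; returns the JSON summary."""
    config.require("alignments_dir", "tree")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    base_tree = LabeledTree.from_file(config.tree)
    domains = read_domain_table(config.domains) if config.domains else None

    aln_paths = sorted(Path(config.alignments_dir).glob("*.fasta"))
    if not aln_paths:
        raise InputError(f"missing_input: no *.fasta in {config.alignments_dir}")

    drop_rows: list[dict] = []
    mask_rows: list[dict] = []
    alignments: dict[str, CodonAlignment] = {}
    policy = TrimPolicy(min_conservation=config.min_conservation)
    for path in aln_paths:
        gene = path.stem
        try:
            aln = CodonAlignment.from_fasta(str(path))
        except ValueError as exc:
            drop_rows.append({"gene_id": gene, "stage": "load", "reason": str(exc)})
            continue
        try:
            trimmed = trim_codon_columns(aln, policy)
        except ValueError as exc:
            drop_rows.append({"gene_id": gene, "stage": "trim", "reason": str(exc)})
            continue
        for col, kept in enumerate(trimmed.mask, start=1):
            if not kept:
                mask_rows.append({"gene_id": gene, "column": col, "retained": 0})
        alignments[gene] = trimmed.alignment

    lrt_results: list[LRTResult] = []
    fits: dict[tuple[str, str], object] = {}
    fit_rows: list[dict] = []
    for model in MODELS:
        fg = design_foreground(config, model)
        tree = base_tree.with_foreground(fg)
        battery: list[LRTResult] = []
        for gene, aln in alignments.items():
            seed = _gene_seed(config.seed, f"{gene}:{model}")
            null, alt = fit_gene(
                aln, tree, gene_id=gene, n_starts=config.n_starts, seed=seed
            )
            fits[(gene, model)] = alt
            for fit in (null, alt):
                m = fit.params.mixture
                fit_rows.append(
                    {
                        "gene_id": gene,
                        "design": model,
                        "model": fit.model,
                        "lnL": fit.lnL,
                        "kappa": fit.params.kappa,
                        "p0": m.p0,
                        "p1": m.p1,
                        "omega0": m.omega0,
                        "omega2": m.omega2,
                        "tree_scale": fit.params.tree_scale,
                        "converged": int(fit.converged),
                    }
                )
            two_delta, p = lrt(null.lnL, alt.lnL)
            battery.append(
                LRTResult(
                    gene_id=gene,
                    model=model,
                    two_delta_L=two_delta,
                    p_value=p,
                    omega2_hat=alt.omega2,
                    converged=null.converged and alt.converged,
                )
            )
        adjust_battery(battery)
        lrt_results.extend(battery)

    calls: dict[str, dict[str, bool]] = {g: {} for g in alignments}
    for r in lrt_results:
        calls[r.gene_id][r.model] = call_psg(
            r, fits.get((r.gene_id, r.model)), fdr_threshold=config.fdr
        )
    partition = partition_psgs(calls)

    # TAAS / EAASPS scan with the calling design's BEB posteriors, for genes
    # called under at least one design
    site_rows = []
    posterior_rows = []
    ext_t_dir = Path(config.extended_target_dir) if config.extended_target_dir else None
    ext_b_dir = (
        Path(config.extended_background_dir)
        if config.extended_background_dir
        else None
    )
    for model in MODELS:
        fg = design_foreground(config, model)
        tree = base_tree.with_foreground(fg)
        targets = design_targets(config, model)
        for gene, aln in alignments.items():
            if not calls[gene].get(model):
                continue
            fit = fits[(gene, model)]
            beb = beb_site_posteriors(aln, tree, fit, grid_size=config.beb_grid)
            posterior_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene,
                        "model": model,
                        "site": np.arange(1, beb.selected.size + 1),
                        "posterior": beb.selected,
                    }
                )
            )
            prot = translate_alignment(aln, lenient=True)
            ext_t = ext_b = None
            if ext_t_dir is not None and (ext_t_dir / f"{gene}.fasta").exists():
                ext_t = ProteinAlignment.from_fasta(str(ext_t_dir / f"{gene}.fasta"))
            if ext_b_dir is not None and (ext_b_dir / f"{gene}.fasta").exists():
                ext_b = ProteinAlignment.from_fasta(str(ext_b_dir / f"{gene}.fasta"))
            records = scan_gene(
                prot,
                [t for t in targets if t in prot.taxa],
                beb.selected,
                extended_target=ext_t,
                extended_background=ext_b,
                domains=domains,
                gene_id=gene,
                pss_cutoff=config.pss_cutoff,
                eaasps_threshold=config.eaasps_threshold,
            )
            df = records_table(records)
            df.insert(1, "model", model)
            site_rows.append(df)

    _write_tsv(pd.DataFrame(drop_rows, columns=["gene_id", "stage", "reason"]),
               out / "filter_report.tsv")
    _write_tsv(pd.DataFrame(mask_rows, columns=["gene_id", "column", "retained"]),
               out / "trim_dropped_columns.tsv")
    _write_tsv(lrt_results_table(lrt_results), out / "lrt_results.tsv")
    _write_tsv(pd.DataFrame(fit_rows), out / "fits.tsv")
    post_df = (
        pd.concat(posterior_rows, ignore_index=True)
        if posterior_rows
        else pd.DataFrame(columns=["gene_id", "model", "site", "posterior"])
    )
    _write_tsv(post_df, out / "site_posteriors.tsv")
    _write_tsv(partition.to_frame(), out / "psg_partition.tsv")
    site_df = (
        pd.concat(site_rows, ignore_index=True)
        if site_rows
        else records_table([]).assign(model=pd.Series(dtype=str))
    )
    _write_tsv(site_df, out / "site_records.tsv")

    summary = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": config.seed,
        "n_genes_input": len(aln_paths),
        "n_genes_analyzed": len(alignments),
        "n_genes_dropped": len(drop_rows),
        "psg_counts": {
            "tetrapod_specific": len(partition.tetrapod_specific),
            "mudskipper_specific": len(partition.mudskipper_specific),
            "union": len(partition.union),
        },
        "n_pss_records": int(site_df["is_pss"].astype(int).sum()) if len(site_df) else 0,
        "n_eaasps": int(
            (site_df["is_eaasps"].astype(str) == "1").sum()
        ) if len(site_df) else 0,
        "thresholds": {
            "fdr": config.fdr,
            "pss_cutoff": config.pss_cutoff,
            "eaasps_threshold": config.eaasps_threshold,
        },
    }
    with open(out / "selection_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# Family pipeline
# ---------------------------------------------------------------------------

def run_family_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Birth-death gene-family pipeline; returns the JSON summary."""
    config.require("family_counts", "time_tree")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tree = LabeledTree.from_file(config.time_tree)
    matrix = read_family_counts(config.family_counts)
    if set(matrix.columns) != set(tree.leaves()):
        raise InputError(
            "missing_input: family matrix species do not match time-tree leaves"
        )
    rpr = tuple(config.root_prior_range) if config.root_prior_range else None
    params, results = analyze_families(
        matrix, tree, n_sim=config.n_sim, seed=config.seed, root_prior_range=rpr
    )
    branch_a = config.foreground_mudskipper
    branch_b = config.foreground_tetrapod
    convergent = convergent_contractions(
        results, branch_a, branch_b, p_threshold=config.family_p
    )
    _write_tsv(family_results_table(results), out / "family_tests.tsv")
    _write_tsv(
        pd.DataFrame({"family_id": sorted(convergent)}),
        out / "convergent_contractions.tsv",
    )
    summary_branches = rapid_branch_summary(results, p_threshold=config.family_p)
    summary_branches.index.name = "branch"
    summary_branches.reset_index().to_csv(
        out / "rapid_branch_summary.tsv", sep="\t", index=False
    )
    if config.species_groups:
        groups = group_count_summary(
            matrix, list(matrix.index), config.species_groups
        )
        groups.reset_index().to_csv(
            out / "group_count_summary.tsv", sep="\t", index=False,
            float_format="%.10g",
        )

    n_rapid = sum(1 for r in results if r.p_value < config.family_p)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": config.seed,
        "n_families": len(results),
        "lambda_hat": params.lambda_,
        "n_rapid_families": n_rapid,
        "rapid_by_branch": {
            str(b): {
                "expansion": int(row.get("expansion", 0)),
                "contraction": int(row.get("contraction", 0)),
            }
            for b, row in summary_branches.iterrows()
        },
        "n_convergent_contractions": len(convergent),
        "convergent_contractions": sorted(convergent),
        "thresholds": {"family_p": config.family_p},
    }
    with open(out / "family_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
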