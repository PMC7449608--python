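"""End-to-end orchestration: normalize -> diversity -> partition -> nulls.

A single :class:`PipelineConfig` drives the whole analysis; one master
seed deterministically derives independent per-stage seeds (via
``numpy.random.SeedSequence(master).spawn``) so any stage can be re-run
in isolation with identical results.  Every stage writes a long-format
tab-delimited table; a JSON manifest records the resolved configuration
and derived stage seeds so a run is fully reproducible from the manifest
alone.  Stages degrade gracefully: without a tree the phylogenetic
stages are skipped with a warning while DS outputs are still produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    CountTable,
    EnvironmentTable,
    PhyloDistances,
    StudyDesign,
    rarefy,
    read_count_table,
    read_design,
    read_environment_table,
    read_tree_distances,
    tree_distances_from_string,
    write_count_table,
)
from .diversity import beta_partition, hill_diversity
from .nullmodel import ds_time_series
from .partition import balance_fractions, split_common_rare
from .phylo import bnti_group, mantel_correlogram, niche_values
from .simulate import ScenarioConfig, simulate_scenario

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ["rarefy", "ds_full", "ds_common", "ds_rare", "bnti", "correlogram"]


@dataclass
class PipelineConfig:
    """Inputs and parameters of one full run.

    Either the four input paths or a :class:`ScenarioConfig` must be
    given.  Numeric defaults are the pipeline's standard operating
    parameters: 10,000 null-model repetitions, 1,000 tip shuffles, 50
    correlogram bins, 1,000 Mantel permutations, 5% FDR, 90% common/rare
    threshold.
    """

    count_table: str | None = None
    design: str | None = None
    tree: str | None = None
    environment: str | None = None
    scenario: ScenarioConfig | None = None
    depth: int | None = None  # rarefaction depth; None = min sample total
    q: float = 0.0
    threshold: float = 0.90
    n_reps: int = 10_000
    n_shuffles: int = 1000
    n_bins: int = 50
    n_perm: int = 1000
    fdr: float = 0.05
    seed: int = 0
    outdir: str = "results/pipeline"


def _stage_seeds(master: int) -> dict[str, int]:
    root = np.random.SeedSequence(master)
    children = root.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        bundle = simulate_scenario(config.scenario)
        dist = tree_distances_from_string(bundle["newick"]) if bundle["newick"] else None
        return bundle["table"], bundle["design"], dist, bundle["environment"], bundle
    if config.count_table is None or config.design is None:
        raise ValueError("either scenario or count_table+design paths are required")
    table = read_count_table(config.count_table)
    design = read_design(config.design)
    dist = read_tree_distances(config.tree) if config.tree else None
    env = read_environment_table(config.environment) if config.environment else None
    return table, design, dist, env, None


def _validate_ids(table: CountTable, design: StudyDesign, dist, env) -> None:
    problems = []
    design_samples = set(design.frame["sample_id"])
    missing = [s for s in table.samples if s not in design_samples]
    if missing:
        problems.append(f"samples missing from design: {missing[:5]}")
    if dist is not None:
        tips = set(dist.tips)
        absent = [f for f in table.features if f not in tips]
        if absent:
            problems.append(f"features missing from tree: {absent[:5]}")
    if env is not None:
        envs = set(env.samples)
        absent = [s for s in table.samples if s not in envs]
        if absent:
            problems.append(f"samples missing from environment table: {absent[:5]}")
    if problems:
        raise ValueError("input validation failed: " + "; ".join(problems))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage, writing tables + manifest to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    table, design, dist, env, bundle = _load_inputs(config)
    _validate_ids(table, design, dist, env)

    # --- depth normalization ------------------------------------------
    totals = table.sample_totals()
    depth = int(config.depth) if config.depth else int(totals.min())
    norm = rarefy(table, depth, seeds["rarefy"])
    write_count_table(norm, outdir / "counts_normalized.tsv")

    # --- diversity profiles -------------------------------------------
    div_rows = [
        {
            "sample_id": s,
            "D0": hill_diversity(norm.column(s), 0),
            "D1": hill_diversity(norm.column(s), 1),
            "D2": hill_diversity(norm.column(s), 2),
        }
        for s in norm.samples
    ]
    pd.DataFrame(div_rows).to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False)

    beta_rows = []
    for (level, day), samples in design.groups():
        if len(samples) < 2:
            continue
        part = beta_partition([norm.column(s) for s in samples], config.q)
        beta_rows.append(
            {
                "level": level,
                "day": day,
                "q": config.q,
                "alpha_bar": part.alpha_bar,
                "gamma": part.gamma,
                "beta": part.beta,
            }
        )
    pd.DataFrame(beta_rows).to_csv(outdir / "beta_partition.tsv", sep="\t", index=False)

    # --- common/rare partition ----------------------------------------
    parts = split_common_rare(norm, config.threshold)
    balanced = None
    try:
        balanced = balance_fractions(parts)
        write_count_table(balanced.common, outdir / "counts_common_balanced.tsv")
        write_count_table(balanced.rare, outdir / "counts_rare.tsv")
        with open(outdir / "normalization_log.json", "w") as fh:
            json.dump(balanced.normalization_log, fh, indent=1)
    except ValueError as exc:
        logger.warning("fraction balancing failed, skipping fraction DS: %s", exc)

    # --- DS null model --------------------------------------------------
    ds_full = ds_time_series(norm, design, config.q, config.n_reps, seeds["ds_full"])
    ds_full.to_csv(outdir / "ds_full.tsv", sep="\t", index=False)
    if balanced is not None:
        ds_time_series(
            balanced.common, design, config.q, config.n_reps, seeds["ds_common"]
        ).to_csv(outdir / "ds_common.tsv", sep="\t", index=False)
        ds_time_series(
            balanced.rare, design, config.q, config.n_reps, seeds["ds_rare"]
        ).to_csv(outdir / "ds_rare.tsv", sep="\t", index=False)

    # --- phylogenetic stages --------------------------------------------
    bnti_summary = None
    if dist is None:
        logger.warning("no tree supplied: skipping betaNTI and correlogram stages")
    else:
        pairs, bnti_summary = bnti_group(
            norm, design, dist, config.n_shuffles, seeds["bnti"]
        )
        pd.DataFrame(
            [
                {
                    "sample_a": r.pair[0],
                    "sample_b": r.pair[1],
                    "bmntd_obs": r.bmntd_obs,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "bnti": r.bnti,
                    "undefined": r.undefined,
                }
                for r in pairs
            ]
        ).to_csv(outdir / "bnti_pairs.tsv", sep="\t", index=False)
        bnti_summary.to_csv(outdir / "bnti_summary.tsv", sep="\t", index=False)
        if env is not None:
            niche = niche_values(norm, env)
            correlogram = mantel_correlogram(
                niche,
                dist,
                n_bins=config.n_bins,
                n_perm=config.n_perm,
                fdr=config.fdr,
                seed=seeds["correlogram"],
            )
            correlogram.to_csv(outdir / "mantel_correlogram.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "depth": depth,
        "stage_seeds": seeds,
        "n_samples": len(table.samples),
        "n_features": len(table.features),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "outdir": outdir,
        "manifest": manifest,
        "ds_full": ds_full,
        "bnti_summary": bnti_summary,
    }
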