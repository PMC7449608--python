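"""Synthetic replicated-bioreactor community generator.

Emulates the study design the pipeline targets: a lognormal metacommunity
of S taxa sampled into n_replicates reactor communities per day at a fixed
sequencing depth, under one of three assembly regimes:

``neutral``
    every replicate is an independent multinomial draw from the shared
    metacommunity (pure sampling drift, no selection);
``divergent``
    each replicate applies its own environmental filter, so selection
    pushes replicate compositions apart (variable selection);
``convergent``
    all replicates share one filter, so selection pulls compositions
    toward the same optimum (homogeneous selection).

Filters come in two parameterizations: random lognormal fitness
w_i(r) = exp(strength * eps_i(r)) with iid standard-normal eps (no tree
needed; exercises the DS stage), or Gaussian trait-environment matching
w_i(r) = exp(-strength * (trait_i - env_r)^2) against a Brownian-motion
trait on a Yule tree (exercises betaNTI and the correlogram, since the
trait is phylogenetically conserved).  ``filter_strength = 0`` reduces
every mode to neutral exactly, bit-for-bit at a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .data import CountTable, EnvironmentTable, StudyDesign, tree_distances

__all__ = [
    "ScenarioConfig",
    "simulate_metacommunity",
    "simulate_tree_and_trait",
    "simulate_replicates",
    "simulate_scenario",
]


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults mirror the replicated-reactor design the pipeline is built
    for: 4 replicate reactors sequenced to 10,000 reads over a 100-taxon
    pool with a lognormal species-abundance distribution of shape 2.
    """

    S: int = 100
    n_replicates: int = 4
    depth: int = 10_000
    sad_sigma: float = 2.0
    filter_strength: float = 0.0
    filter_mode: str = "neutral"  # neutral | divergent | convergent
    tree_birth_rate: float = 1.0
    trait_sigma: float = 1.0
    use_tree: bool = False  # trait-environment matching instead of random fitness
    drift_sigma: float = 0.0  # per-replicate lognormal fitness noise on top of the filter
    env_series: list[float] | None = None  # one env optimum per replicate
    env_quantile: float = 0.5  # trait quantile of the shared optimum (trait-matching modes)
    n_days: int = 1
    level: str = "L"
    press_day: int | None = None  # day at which env switches to press_env
    press_env: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_mode not in ("neutral", "divergent", "convergent"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.S < 1 or self.depth < 1 or self.n_replicates < 1 or self.n_days < 1:
            raise ValueError("S, depth, n_replicates, n_days must be >= 1")
        if self.sad_sigma < 0 or self.filter_strength < 0:
            raise ValueError("sad_sigma and filter_strength must be >= 0")


def _seeds(config: ScenarioConfig) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(config.seed)
    names = ["metacommunity", "tree", "trait", "filter", "sampling"]
    return dict(zip(names, root.spawn(len(names))))


def _taxon_labels(S: int) -> list[str]:
    width = len(str(S))
    return [f"t{i + 1:0{width}d}" for i in range(S)]


def simulate_metacommunity(config: ScenarioConfig) -> np.ndarray:
    """Relative abundances ~ lognormal(0, sad_sigma), normalized to sum 1."""
    rng = np.random.default_rng(_seeds(config)["metacommunity"])
    if config.sad_sigma == 0:
        return np.full(config.S, 1.0 / config.S)
    raw = rng.lognormal(mean=0.0, sigma=config.sad_sigma, size=config.S)
    return raw / raw.sum()


def simulate_tree_and_trait(config: ScenarioConfig) -> tuple[str, pd.Series]:
    """Yule tree with S tips plus a Brownian-motion trait (root value 0).

    Returns the Newick string and a Series of tip trait values indexed by
    tip label.
    """
    if config.S < 2:
        raise ValueError("need S >= 2 for a tree")
    seeds = _seeds(config)
    tree_rng = random.Random(int(seeds["tree"].generate_state(1)[0]))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=config.tree_birth_rate,
        death_rate=0.0,
        num_extant_tips=config.S,
        rng=tree_rng,
    )
    # the simulation stops exactly at the S-th speciation, leaving the newest
    # cherry with zero-length tip branches; extend every pendant edge by the
    # waiting time to the next (unrealized) birth event
    extra = tree_rng.expovariate(config.tree_birth_rate * config.S)
    labels = _taxon_labels(config.S)
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = label

    rng = np.random.default_rng(seeds["trait"])
    trait: dict[str, float] = {}
    values = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        step = rng.normal(0.0, config.trait_sigma * np.sqrt(edge)) if config.trait_sigma > 0 else 0.0
        values[node] = values[node.parent_node] + step
        if node.is_leaf():
            trait[node.taxon.label] = values[node]
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, pd.Series({lbl: trait[lbl] for lbl in labels}, name="trait")


def _env_optima(config: ScenarioConfig, trait: pd.Series | None, rng) -> np.ndarray:
    """One environmental optimum per replicate."""
    if config.env_series is not None:
        env = np.asarray(config.env_series, dtype=float)
        if env.size != config.n_replicates:
            raise ValueError("env_series must have one value per replicate")
        return env
    if trait is not None:
        vals = trait.to_numpy()
        if config.filter_mode == "divergent":
            # spread optima across the trait range so replicates select
            # different clades
            qs = np.linspace(0.1, 0.9, config.n_replicates)
            return np.quantile(vals, qs)
        return np.full(config.n_replicates, float(np.quantile(vals, config.env_quantile)))
    return np.zeros(config.n_replicates)


def simulate_replicates(
    config: ScenarioConfig,
    metacommunity: np.ndarray,
    trait: pd.Series | None = None,
) -> tuple[CountTable, StudyDesign, EnvironmentTable]:
    """Replicated count table + design + per-sample environment.

    Each sample is a multinomial draw of ``depth`` reads from the
    filter-weighted metacommunity; days are independent draws.  With a
    press disturbance configured, the environmental optimum switches to
    ``press_env`` from ``press_day`` onward (trait-matching mode).
    """
    meta = np.asarray(metacommunity, dtype=float)
    if meta.size != config.S:
        raise ValueError("metacommunity size does not match config.S")
    seeds = _seeds(config)
    rng_filter = np.random.default_rng(seeds["filter"])
    rng_sample = np.random.default_rng(seeds["sampling"])
    labels = _taxon_labels(config.S)
    trait_vals = trait.reindex(labels).to_numpy() if trait is not None else None

    env0 = _env_optima(config, trait, rng_filter)
    # random-fitness noise: per replicate, drawn once (a fixed selective
    # environment per reactor), shared across replicates in convergent mode
    eps = rng_filter.standard_normal((config.n_replicates, config.S))
    if config.filter_mode == "convergent":
        eps = np.tile(eps[0], (config.n_replicates, 1))
    # independent reactor-to-reactor fitness noise (ecological drift between
    # replicate reactors), drawn regardless of mode for stream stability
    drift = rng_filter.standard_normal((config.n_replicates, config.S))

    columns, names, rows_design, env_rows = [], [], [], []
    days = list(range(1, config.n_days + 1))
    for day in days:
        env = env0.copy()
        if config.press_day is not None and day >= config.press_day:
            env[:] = config.press_env if config.press_env is not None else env0
        for r in range(config.n_replicates):
            if config.filter_mode == "neutral" or config.filter_strength == 0:
                w = np.ones(config.S)
            elif trait_vals is not None and config.use_tree:
                w = np.exp(-config.filter_strength * (trait_vals - env[r]) ** 2)
            else:
                w = np.exp(config.filter_strength * eps[r])
            if config.drift_sigma > 0:
                w = w * np.exp(config.drift_sigma * drift[r])
            p = meta * w
            p = p / p.sum()
            counts = rng_sample.multinomial(config.depth, p)
            name = f"R{r + 1}_d{day:03d}"
            names.append(name)
            columns.append(counts)
            rows_design.append(
                {"sample_id": name, "reactor": f"R{r + 1}", "level": config.level, "day": day}
            )
            env_rows.append({"sample": name, "env": float(env[r])})

    table = CountTable(labels, names, np.column_stack(columns), feature_kind="ASV")
    design = StudyDesign(pd.DataFrame(rows_design))
    env_table = EnvironmentTable(pd.DataFrame(env_rows).set_index("sample"))
    return table, design, env_table


def simulate_scenario(config: ScenarioConfig) -> dict:
    """End-to-end scenario bundle: table, design, environment, tree, trait.

    The tree and trait are generated whenever ``use_tree`` is set (they
    drive the filter) and always when S >= 2, so phylogenetic stages are
    exercisable on any scenario.
    """
    meta = simulate_metacommunity(config)
    newick, trait = (None, None)
    if config.S >= 2:
        newick, trait = simulate_tree_and_trait(config)
    table, design, env = simulate_replicates(config, meta, trait)
    return {
        "config": asdict(config),
        "metacommunity": meta,
        "newick": newick,
        "trait": trait,
        "table": table,
        "design": design,
        "environment": env,
    }
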