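"""Individual-shuffling beta-partition null model and deterministic strength.

The null hypothesis is ecological equivalence of individuals: reads from
all replicate reactors of one treatment group are pooled and redistributed
uniformly at random back into samples of the original sizes.  Each
realization preserves per-reactor totals, the pooled relative abundance of
every taxon, and hence gamma-diversity; only the between-replicate
placement of individuals is randomized.  Comparing the observed
beta-partition with the null distribution gives

    DS    = |beta_obs - mean(beta_null)| / beta_obs   (deterministic strength)
    SI    = 1 - DS                                    (stochastic intensity)
    ratio = mean(beta_null) / beta_obs                (expected:observed)

Higher DS means observed replicate turnover deviates more from the random
placement expectation, i.e. a stronger deterministic assembly signal; a
ratio below 1 means observed beta-diversity exceeds the chance expectation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountTable, StudyDesign
from .diversity import beta_partition, hill_diversity

__all__ = ["NullModelResult", "shuffle_individuals", "run_null_model", "ds_time_series"]

logger = logging.getLogger(__name__)


@dataclass
class NullModelResult:
    beta_obs: float
    beta_exp_mean: float
    beta_exp_sd: float
    n_reps: int
    ds: float  # NaN when beta_obs == 0
    si: float
    ratio: float
    undefined: bool = False
    null_betas: np.ndarray | None = None


def _validate_group(group_samples) -> np.ndarray:
    mat = np.asarray(group_samples)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 samples (rows) of equal length")
    if not np.issubdtype(mat.dtype, np.integer):
        as_int = mat.astype(np.int64)
        if not np.array_equal(as_int, mat):
            raise ValueError("null model requires integer counts")
        mat = as_int
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    return mat.astype(np.int64)


def shuffle_individuals(group_samples, seed=None, rng=None) -> list[np.ndarray]:
    """One null realization: redistribute pooled individuals into samples.

    Equivalent to partitioning the pooled multiset of reads uniformly at
    random into parts of the original sample sizes; implemented as
    sequential multivariate-hypergeometric draws without replacement.
    """
    mat = _validate_group(group_samples)
    if rng is None:
        rng = np.random.default_rng(seed)
    remaining = mat.sum(axis=0)
    sizes = mat.sum(axis=1)
    out: list[np.ndarray] = []
    for n in sizes[:-1]:
        draw = rng.multivariate_hypergeometric(remaining, int(n), method="marginals")
        out.append(draw)
        remaining = remaining - draw
    out.append(remaining)
    return out


def run_null_model(
    group_samples,
    q: float = 0.0,
    n_reps: int = 10_000,
    seed=None,
    keep_null: bool = False,
) -> NullModelResult:
    """Observed beta-partition vs the individual-shuffle null distribution."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mat = _validate_group(group_samples)
    rng = np.random.default_rng(seed)

    obs = beta_partition(list(mat), q)
    # gamma is invariant under shuffling (pooled counts conserved exactly)
    gamma = obs.gamma
    k = mat.shape[0]

    null = np.empty(n_reps)
    for r in range(n_reps):
        draws = shuffle_individuals(mat, rng=rng)
        alpha_bar = math.fsum(hill_diversity(d, q) for d in draws) / k
        null[r] = 1.0 - alpha_bar / gamma

    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_reps > 1 else 0.0
    if obs.beta > 0:
        ds = abs(obs.beta - mean) / obs.beta
        result = NullModelResult(
            beta_obs=obs.beta,
            beta_exp_mean=mean,
            beta_exp_sd=sd,
            n_reps=n_reps,
            ds=ds,
            si=1.0 - ds,
            ratio=mean / obs.beta,
            null_betas=null if keep_null else None,
        )
    else:
        result = NullModelResult(
            beta_obs=obs.beta,
            beta_exp_mean=mean,
            beta_exp_sd=sd,
            n_reps=n_reps,
            ds=float("nan"),
            si=float("nan"),
            ratio=float("nan"),
            undefined=True,
            null_betas=null if keep_null else None,
        )
    return result


def ds_time_series(
    table: CountTable,
    design: StudyDesign,
    q: float = 0.0,
    n_reps: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """One NullModelResult row per (level, day) group, sorted by phase then day.

    Groups with fewer than two samples are skipped with a warning.  Each
    group gets an independent child seed derived from ``seed`` so groups
    can be recomputed in isolation.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for (level, day), samples in design.groups():
        child = np.random.default_rng(ss.spawn(1)[0])
        if len(samples) < 2:
            logger.warning("skipping group (%s, %s): fewer than 2 samples", level, day)
            continue
        idx = [table.samples.index(s) for s in samples]
        group = table.counts[:, idx].T
        res = run_null_model(group, q=q, n_reps=n_reps, seed=child)
        rows.append(
            {
                "level": level,
                "day": day,
                "n_samples": len(samples),
                "beta_obs": res.beta_obs,
                "beta_exp_mean": res.beta_exp_mean,
                "beta_exp_sd": res.beta_exp_sd,
                "DS": res.ds,
                "SI": res.si,
                "ratio": res.ratio,
                "n_reps": res.n_reps,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "level",
            "day",
            "n_samples",
            "beta_obs",
            "beta_exp_mean",
            "beta_exp_sd",
            "DS",
            "SI",
            "ratio",
            "n_reps",
        ],
    )
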