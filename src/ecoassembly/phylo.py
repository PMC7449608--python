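"""Abundance-weighted betaMNTD, tip-shuffle betaNTI, and phylogenetic signal.

betaMNTD between communities x and y is the abundance-weighted mean
patristic distance from each taxon to its nearest relative in the other
community:

    betaMNTD = 1/2 [ sum_i f_i min_j d(i, j) + sum_j f_j min_i d(j, i) ]

with f the relative abundances within each community; taxa shared by both
communities contribute distance zero.  The null model shuffles the
taxon-to-tip assignment (one global permutation applied to both
communities, preserving abundances and taxon sharing); the standardized
effect size

    betaNTI = (betaMNTD_obs - mean_null) / sd_null

is read against the conventional +/-2 threshold: |betaNTI| > 2 indicates
significantly deterministic turnover (negative: communities are more
phylogenetically similar than chance, the homogeneous-selection
signature; positive: variable selection), |betaNTI| < 2 is consistent
with stochastic assembly.

The method assumes niches are phylogenetically conserved at short
distances; the Mantel correlogram between taxon niche differences and
binned phylogenetic distances checks that assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import CountTable, EnvironmentTable, PhyloDistances, StudyDesign

__all__ = [
    "BetaNTIResult",
    "bmntd",
    "bnti",
    "bnti_group",
    "niche_values",
    "mantel_correlogram",
]

logger = logging.getLogger(__name__)

BNTI_THRESHOLD = 2.0


def _weights(v: np.ndarray, weighted: bool, idx: np.ndarray) -> np.ndarray:
    if weighted:
        return v[idx] / v[idx].sum()
    return np.full(idx.size, 1.0 / idx.size)


def _bmntd_from_submatrix(dxy: np.ndarray, fx: np.ndarray, fy: np.ndarray) -> float:
    return 0.5 * (fx @ dxy.min(axis=1) + fy @ dxy.min(axis=0))


def bmntd(x, y, dist: PhyloDistances, taxa: list[str], weighted: bool = True) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two communities.

    ``taxa`` names the entries of ``x`` and ``y``; all taxa with nonzero
    counts must be tips of ``dist``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix = np.flatnonzero(x)
    iy = np.flatnonzero(y)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("both communities must be nonzero")
    tip_idx = dist.indices_of([taxa[i] for i in np.union1d(ix, iy)])
    lookup = dict(zip(np.union1d(ix, iy).tolist(), tip_idx.tolist()))
    rows = np.array([lookup[i] for i in ix], dtype=np.intp)
    cols = np.array([lookup[j] for j in iy], dtype=np.intp)
    dxy = dist.dist[np.ix_(rows, cols)]
    return float(_bmntd_from_submatrix(dxy, _weights(x, weighted, ix), _weights(y, weighted, iy)))


@dataclass
class BetaNTIResult:
    pair: tuple[str, str]
    bmntd_obs: float
    null_mean: float
    null_sd: float
    bnti: float  # NaN when the null is degenerate
    n_shuffles: int
    undefined: bool = False


def bnti(
    x,
    y,
    dist: PhyloDistances,
    taxa: list[str],
    n_shuffles: int = 1000,
    seed=None,
    weighted: bool = True,
    pair: tuple[str, str] = ("x", "y"),
) -> BetaNTIResult:
    """betaNTI for one community pair against the tip-shuffle null.

    Each shuffle draws a uniform random permutation of the taxon-to-tip
    assignment over all tips of the tree (the same permutation for both
    communities) and recomputes betaMNTD.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ix = np.flatnonzero(x)
    iy = np.flatnonzero(y)
    if np.union1d(ix, iy).size < 3:
        raise ValueError("need >= 3 distinct taxa across the pair")
    rng = np.random.default_rng(seed)

    tix = dist.indices_of([taxa[i] for i in ix])
    tiy = dist.indices_of([taxa[j] for j in iy])
    fx = _weights(x, weighted, ix)
    fy = _weights(y, weighted, iy)
    D = dist.dist
    obs = _bmntd_from_submatrix(D[np.ix_(tix, tiy)], fx, fy)

    n_tips = len(dist.tips)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(n_tips)
        null[s] = _bmntd_from_submatrix(D[np.ix_(perm[tix], perm[tiy])], fx, fy)

    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    if sd > 0:
        return BetaNTIResult(pair, float(obs), mean, sd, (obs - mean) / sd, n_shuffles)
    return BetaNTIResult(pair, float(obs), mean, sd, float("nan"), n_shuffles, undefined=True)


def bnti_group(
    table: CountTable,
    design: StudyDesign,
    dist: PhyloDistances,
    n_shuffles: int = 1000,
    seed=None,
    weighted: bool = True,
) -> tuple[list[BetaNTIResult], pd.DataFrame]:
    """betaNTI for every within-(level, day) sample pair, plus group summaries.

    Returns the pairwise results and a per-group frame with the mean
    betaNTI and counts of deterministic (|betaNTI| > 2) vs stochastic
    pairs for each time point.
    """
    ss = np.random.SeedSequence(seed)
    results: list[BetaNTIResult] = []
    rows = []
    for (level, day), samples in design.groups():
        child = np.random.default_rng(ss.spawn(1)[0])
        if len(samples) < 2:
            logger.warning("skipping group (%s, %s): fewer than 2 samples", level, day)
            continue
        vals = []
        for sa, sb in combinations(samples, 2):
            res = bnti(
                table.column(sa),
                table.column(sb),
                dist,
                table.features,
                n_shuffles=n_shuffles,
                seed=child,
                weighted=weighted,
                pair=(sa, sb),
            )
            results.append(res)
            if not res.undefined:
                vals.append(res.bnti)
        vals = np.asarray(vals)
        rows.append(
            {
                "level": level,
                "day": day,
                "n_pairs": len(list(combinations(samples, 2))),
                "mean_bnti": float(vals.mean()) if vals.size else float("nan"),
                "n_deterministic": int((np.abs(vals) > BNTI_THRESHOLD).sum()),
                "n_stochastic": int((np.abs(vals) <= BNTI_THRESHOLD).sum()),
            }
        )
    summary = pd.DataFrame(
        rows, columns=["level", "day", "n_pairs", "mean_bnti", "n_deterministic", "n_stochastic"]
    )
    return results, summary


def niche_values(table: CountTable, env: EnvironmentTable) -> pd.DataFrame:
    """Abundance-weighted mean environment per taxon (taxa x variables).

    niche(taxon, var) = sum_s relabund(taxon, s) * env(s, var)
                        / sum_s relabund(taxon, s)

    Taxa with zero total abundance over the shared samples are dropped
    with a warning.
    """
    shared = [s for s in table.samples if s in set(env.samples)]
    if not shared:
        raise ValueError("no samples shared between count table and environment table")
    idx = [table.samples.index(s) for s in shared]
    counts = table.counts[:, idx].astype(float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("shared samples must be nonempty")
    rel = counts / totals
    envmat = env.frame.loc[shared].to_numpy(dtype=float)
    wsum = rel.sum(axis=1)
    keep = wsum > 0
    if not keep.all():
        logger.warning("dropping %d taxa with zero abundance", int((~keep).sum()))
    niche = (rel[keep] @ envmat) / wsum[keep, None]
    return pd.DataFrame(
        niche, index=[f for f, k in zip(table.features, keep) if k], columns=env.variables
    )


def _niche_distance_matrix(niche: pd.DataFrame) -> np.ndarray:
    vals = niche.to_numpy(dtype=float)
    if vals.shape[1] > 1:
        sd = vals.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        vals = (vals - vals.mean(axis=0)) / sd
    diff = vals[:, None, :] - vals[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def mantel_correlogram(
    niche: pd.DataFrame,
    dist: PhyloDistances,
    n_bins: int = 50,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Phylogenetic Mantel correlogram of taxon niche differences.

    Phylogenetic distances are cut into ``n_bins`` equal-width classes
    over [0, max]; for each class the Mantel statistic is the negative
    Pearson correlation between the niche-difference vector and the
    within-class indicator over all taxon pairs, so positive values mean
    taxa in that distance class have more similar niches than average
    (a Moran's-I-like reading).  Significance is assessed by permuting
    taxon identities of the niche values ``n_perm`` times (two-sided),
    with Benjamini-Hochberg adjustment at ``fdr`` across non-empty,
    non-degenerate bins.
    """
    taxa = [str(t) for t in niche.index]
    if len(taxa) < 10:
        raise ValueError("need >= 10 taxa for the correlogram")
    tip_idx = dist.indices_of(taxa)
    P = dist.dist[np.ix_(tip_idx, tip_idx)]
    N = _niche_distance_matrix(niche)

    n = len(taxa)
    iu = np.triu_indices(n, k=1)
    pvec = P[iu]
    nvec = N[iu]

    edges = np.linspace(0.0, pvec.max(), n_bins + 1)
    # right-inclusive bins; the first bin also includes distance 0
    which = np.clip(np.searchsorted(edges, pvec, side="left") - 1, 0, n_bins - 1)
    indicators = np.zeros((n_bins, pvec.size))
    for b in range(n_bins):
        indicators[b, which == b] = 1.0

    n_pairs_per_bin = indicators.sum(axis=1).astype(int)
    valid = (n_pairs_per_bin > 0) & (n_pairs_per_bin < pvec.size) & (nvec.std() > 0)

    def corr_rows(vec: np.ndarray) -> np.ndarray:
        vc = vec - vec.mean()
        mc = indicators - indicators.mean(axis=1, keepdims=True)
        denom = np.sqrt((vc**2).sum()) * np.sqrt((mc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return -(mc @ vc) / denom

    r_obs = corr_rows(nvec)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_bins)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr_rows(N[np.ix_(perm, perm)][iu])
        exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-12
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    p_adj = np.full(n_bins, np.nan)
    signif = np.zeros(n_bins, dtype=bool)
    if valid.any():
        rej, adj, _, _ = multipletests(pvals[valid], alpha=fdr, method="fdr_bh")
        p_adj[valid] = adj
        signif[valid] = rej

    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "dist_low": edges[:-1],
            "dist_high": edges[1:],
            "n_pairs": n_pairs_per_bin,
            "r": np.where(valid, r_obs, np.nan),
            "p": np.where(valid, pvals, np.nan),
            "p_adj": p_adj,
            "significant": signif,
            "valid": valid,
        }
    )
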