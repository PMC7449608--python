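"""Common/rare abundance partitioning and sampling-effort balancing.

Per sample, features are ranked by descending count and the minimal
prefix accumulating at least 90% of that sample's reads (the crossing
feature included) is the common fraction; the remainder is rare.  The
per-sample fractions are compiled into two matrices over the full feature
list, so common + rare reconstructs every sample column exactly.

Because abundant taxa are near-deterministically spread over a handful of
reactors by sheer numbers, DS comparisons between fractions require equal
sampling effort: the common matrix is rescaled per sample to the rare
matrix's total using largest-remainder integer apportionment with a floor
of one read on every nonzero feature, so no community member is lost and
relative abundances are distorted as little as integrality allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CountTable

__all__ = ["PartitionedTables", "split_common_rare", "balance_fractions"]


@dataclass
class PartitionedTables:
    common: CountTable
    rare: CountTable
    threshold: float
    normalization_log: list[dict] = field(default_factory=list)


def split_common_rare(
    table: CountTable, threshold: float = 0.90, per_sample: bool = True
) -> PartitionedTables:
    """Two-way partition of each sample column at the accumulated-read threshold.

    ``per_sample=False`` ranks on dataset-wide accumulated reads instead,
    classifying each feature globally.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    counts = table.counts
    totals = counts.sum(axis=0)
    empty = [s for s, t in zip(table.samples, totals) if t == 0]
    if empty:
        raise ValueError(f"empty samples: {empty}")

    feats = np.array(table.features)
    common = np.zeros_like(counts)

    def common_mask(col: np.ndarray, total: int) -> np.ndarray:
        nz = np.flatnonzero(col)
        # descending count, ties broken lexicographically by feature ID
        order = nz[np.lexsort((feats[nz], -col[nz]))]
        cum = np.cumsum(col[order])
        k = int(np.searchsorted(cum, threshold * total)) + 1
        mask = np.zeros(col.shape, dtype=bool)
        mask[order[:k]] = True
        return mask

    if per_sample:
        for j in range(counts.shape[1]):
            m = common_mask(counts[:, j], totals[j])
            common[m, j] = counts[m, j]
    else:
        pooled = counts.sum(axis=1)
        m = common_mask(pooled, pooled.sum())
        common[m, :] = counts[m, :]

    rare = counts - common
    return PartitionedTables(
        common=CountTable(list(table.features), list(table.samples), common, table.feature_kind),
        rare=CountTable(list(table.features), list(table.samples), rare, table.feature_kind),
        threshold=threshold,
    )


def _apportion_floor1(counts: np.ndarray, target: int, feature_ids: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``target`` units with floor 1.

    Every nonzero entry keeps at least one unit; totals match ``target``
    exactly.  Ties in remainders break lexicographically by feature ID.
    """
    out = np.zeros_like(counts)
    nz = np.flatnonzero(counts)
    m = nz.size
    if m == 0:
        if target != 0:
            raise ValueError("cannot apportion positive target over empty column")
        return out
    if target < m:
        raise ValueError(
            f"target {target} smaller than nonzero richness {m}: no floor-1 apportionment"
        )
    quota = counts[nz] * (target / counts[nz].sum())
    alloc = np.maximum(1, np.floor(quota).astype(np.int64))
    diff = target - int(alloc.sum())
    rem = quota - alloc
    if diff > 0:
        order = np.lexsort((feature_ids[nz], -rem))
        alloc[order[:diff]] += 1
    while diff < 0:
        # overflow from raising sub-quota entries to the floor: take back
        # units from entries above 1, least-deserving (smallest remainder) first
        eligible = np.flatnonzero(alloc > 1)
        order = eligible[np.lexsort((feature_ids[nz][eligible], rem[eligible]))]
        take = order[: min(-diff, order.size)]
        alloc[take] -= 1
        rem[take] += 1.0
        diff += take.size
    out[nz] = alloc
    return out


def balance_fractions(p: PartitionedTables, seed=None) -> PartitionedTables:
    """Rescale the common matrix per sample to the rare matrix's total.

    Deterministic (``seed`` accepted for interface symmetry but unused:
    apportionment ties are broken by feature ID).  Raises if any sample's
    rare total is below its nonzero common richness, in which case no
    floor-1 apportionment exists.
    """
    common = p.common.counts
    rare_totals = p.rare.counts.sum(axis=0)
    feats = np.array(p.common.features)
    out = np.zeros_like(common)
    log: list[dict] = []
    for j, sample in enumerate(p.common.samples):
        col = common[:, j]
        target = int(rare_totals[j])
        richness = int((col > 0).sum())
        if target < richness:
            raise ValueError(
                f"sample {sample!r}: rare total {target} < common richness "
                f"{richness}; cannot balance without losing members"
            )
        if col.sum() == target:
            out[:, j] = col
        else:
            out[:, j] = _apportion_floor1(col, target, feats)
        log.append(
            {
                "sample": sample,
                "common_total_before": int(col.sum()),
                "target_total": target,
                "common_total_after": int(out[:, j].sum()),
                "n_members": richness,
                "max_abs_share_shift": float(
                    np.max(
                        np.abs(
                            out[:, j] / max(target, 1) - col / max(col.sum(), 1)
                        )
                    )
                )
                if richness
                else 0.0,
            }
        )
    balanced = CountTable(
        list(p.common.features), list(p.common.samples), out, p.common.feature_kind
    )
    return PartitionedTables(
        common=balanced, rare=p.rare, threshold=p.threshold, normalization_log=log
    )
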