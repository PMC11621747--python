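"""Cultural fixation index (CFST) over a grouped population of discrete variants.

The cultural analogue of Wright's FST: the proportion of total variant
heterogeneity in a metapopulation attributable to differences *between*
groups rather than within them,

    CFST = (H_T - H_S) / H_T,

where ``H_T = 1 - sum_i pbar_i**2`` is the pooled ("total") heterogeneity and
``H_S`` is the unweighted mean across groups of the within-group
heterogeneity ``1 - sum_i p_{g,i}**2``. Naive individuals (holding no
variant) are excluded before counting.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["cfst", "cfst_from_matrix", "counts_from_snapshot"]


def cfst_from_matrix(counts: np.ndarray) -> float:
    """CFST from a (n_groups, n_variants) matrix of nonnegative counts.

    Groups with zero total (e.g. all-naive groups) are dropped before
    computing either heterogeneity. Returns 0.0 when the pooled population
    is fixed on a single variant (H_T = 0): no variation anywhere. With
    equal group totals H_T >= H_S always (Jensen); with unequal totals the
    unweighted descriptive index can dip marginally below zero and is
    truncated at 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D group x variant matrix")
    if np.any(counts < 0):
        raise ValueError("variant counts must be nonnegative")
    totals = counts.sum(axis=1)
    counts = counts[totals > 0]
    totals = totals[totals > 0]
    if counts.shape[0] < 2:
        raise ValueError("CFST requires at least two groups with variants")
    freqs = counts / totals[:, None]
    h_within = 1.0 - np.sum(freqs**2, axis=1)
    h_s = float(h_within.mean())
    pooled = counts.sum(axis=0)
    pbar = pooled / pooled.sum()
    h_t = float(1.0 - np.sum(pbar**2))
    if h_t == 0.0:
        return 0.0
    return max((h_t - h_s) / h_t, 0.0)


def cfst(grouped_counts: Mapping[object, Mapping[object, float]]) -> float:
    """CFST from a mapping ``group -> {variant: count}``.

    Invariant to variant labels and group order; scaling every count by a
    common positive factor leaves the value unchanged.
    """
    groups = list(grouped_counts)
    variants = sorted({v for g in groups for v in grouped_counts[g]}, key=repr)
    vindex = {v: j for j, v in enumerate(variants)}
    mat = np.zeros((len(groups), max(len(variants), 1)))
    for i, g in enumerate(groups):
        for v, c in grouped_counts[g].items():
            mat[i, vindex[v]] = c
    return cfst_from_matrix(mat)


def counts_from_snapshot(snapshot: pd.DataFrame, naive: int = -1) -> np.ndarray:
    """Group x variant count matrix from a population snapshot.

    Expects columns ``group`` and ``variant``; rows with ``variant == naive``
    are excluded. Group rows are indexed 0..max(group).
    """
    df = snapshot[snapshot["variant"] != naive]
    n_groups = int(snapshot["group"].max()) + 1
    codes, _ = pd.factorize(df["variant"], sort=True)
    mat = np.zeros((n_groups, max(codes.max() + 1, 1) if len(codes) else 1))
    np.add.at(mat, (df["group"].to_numpy(), codes), 1.0)
    return mat
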