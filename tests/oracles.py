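"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written in the most naive way possible (explicit loops,
per-row arithmetic, full sorts) and never calls into the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

NAIVE = -1


def adoption_probs_bruteforce(variant_counts: dict, theta: float) -> dict:
    """Normalize n**theta by direct summation."""
    weights = {}
    total = 0.0
    for v, c in variant_counts.items():
        if c > 0:
            w = float(c) ** theta
            weights[v] = w
            total += w
    return {v: w / total for v, w in weights.items()}


def cfst_bruteforce(grouped_counts: dict) -> float:
    """Heterozygosities by explicit double loops over groups and variants."""
    variants = set()
    for g in grouped_counts:
        for v in grouped_counts[g]:
            variants.add(v)
    groups = [g for g in grouped_counts if sum(grouped_counts[g].values()) > 0]
    h_within = []
    for g in groups:
        total = sum(grouped_counts[g].values())
        ss = 0.0
        for v in variants:
            p = grouped_counts[g].get(v, 0) / total
            ss += p * p
        h_within.append(1.0 - ss)
    h_s = sum(h_within) / len(h_within)
    grand = 0.0
    for g in groups:
        grand += sum(grouped_counts[g].values())
    ss = 0.0
    for v in variants:
        pooled = sum(grouped_counts[g].get(v, 0) for g in groups) / grand
        ss += pooled * pooled
    h_t = 1.0 - ss
    if h_t == 0.0:
        return 0.0
    return (h_t - h_s) / h_t


def panel_loglik_bruteforce(panel, mu, theta, m_rates, boundaries) -> float:
    """Per-row re-evaluation of the transmission likelihood."""
    total = 0.0
    rec = panel.records
    for i in range(len(rec)):
        row = rec.iloc[i]
        age_class = 0
        for k, b in enumerate(boundaries):
            if row["age"] >= b:
                age_class = k
        m = m_rates[age_class]
        total += math.log(m) if row["migrated"] else math.log(1 - m)
        if row["learned"]:
            total += math.log(mu) if row["innovated"] else math.log(1 - mu)
            if not row["innovated"] and row["variant"] != NAIVE:
                tally: dict = {}
                for v in panel.contacts[i]:
                    if v != NAIVE:
                        tally[v] = tally.get(v, 0) + 1
                if row["prev_variant"] != NAIVE:
                    tally[row["prev_variant"]] = tally.get(row["prev_variant"], 0) + 1
                denom = sum(float(c) ** theta for c in tally.values())
                total += math.log(float(tally[row["variant"]]) ** theta / denom)
    return total


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Coefficients and classical SEs of y ~ [1, x] by solving X'X b = X'y."""
    design = np.column_stack([np.ones(len(y)), x])
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    dof = len(y) - design.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    return beta, se


def rejection_abc_bruteforce(draws, summaries, reference, n_keep):
    """Full stable sort of |summary - reference|; returns kept indices."""
    dist = [abs(s - reference) for s in summaries]
    order = sorted(range(len(draws)), key=lambda i: (dist[i], i))
    return order[:n_keep]
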