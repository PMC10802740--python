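"""Tumor-vs-normal exon statistics: U, its normal approximation, rank
weights, and the weighted Stouffer composite.

For tumor values X1..Xn1 and normal values Y1..Yn2 the pair statistic is
U = sum_ij S(Xi, Yj) with S = 1 if Y < X, 1/2 if Y = X, 0 if Y > X — the
Mann-Whitney U with half-credit for ties.  Under the null,
mU = n1 n2 / 2 and sigmaU = sqrt(n1 n2 (n1 + n2 + 1) / 12) (no tie
correction in the default variant), giving z = (U - mU) / sigmaU.

Each (tumor type, normal tissue) pair contributes a z and a weight
w = median(rank(X)) - median(rank(Y)) in percentile-rank space; the
per-exon composite over k pairs is sum(w_i z_i) / sqrt(sum(w_i^2)),
which is unit-variance under the null for fixed weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .quant import percentile_ranks


def u_statistic(x, y) -> float:
    """Rank-based U; equals the O(n1*n2) pairwise enumeration with ties at 1/2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def u_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise U for an exon x sample block pair (same exons, two groups)."""
    n1 = X.shape[1]
    ranks = rankdata(np.concatenate([X, Y], axis=1), axis=1, method="average")
    return ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0


def z_from_u(U, n1: int, n2: int):
    """Normal approximation of U; no tie correction in sigma."""
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    mU = n1 * n2 / 2.0
    sigmaU = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (np.asarray(U, dtype=float) - mU) / sigmaU


def z_from_u_tie_corrected(U, x, y):
    """Tie-corrected sigma variant, for sensitivity analysis only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    n = n1 + n2
    _, t = np.unique(np.concatenate([x, y]), return_counts=True)
    correction = ((t ** 3 - t).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - correction))
    if sigma == 0:
        return 0.0
    return float((U - n1 * n2 / 2.0) / sigma)


def pair_weight(pr_x, pr_y) -> float:
    """Median percentile-rank differential between tumor and normal samples."""
    pr_x = np.asarray(pr_x, dtype=float)
    pr_y = np.asarray(pr_y, dtype=float)
    if pr_x.size == 0 or pr_y.size == 0:
        raise ValueError("both rank groups must be non-empty")
    return float(np.median(pr_x) - np.median(pr_y))


def composite_z(zs, ws) -> tuple[float, bool]:
    """Weighted Stouffer combination: sum(w z) / sqrt(sum(w^2)).

    Returns (composite, degenerate_flag); an all-zero weight vector gives
    0 with the degenerate flag set.
    """
    zs = np.asarray(zs, dtype=float)
    ws = np.asarray(ws, dtype=float)
    if zs.shape != ws.shape:
        raise ValueError("zs and ws must have the same length")
    if zs.size == 0:
        raise ValueError("need at least one pair")
    denom = np.sqrt((ws ** 2).sum())
    if denom == 0:
        return 0.0, True
    return float((ws * zs).sum() / denom), False


def compartment_samples(samples: pd.DataFrame, compartment: str) -> list[str]:
    """Tumor samples of the compartment plus all normal samples."""
    mask = (samples["compartment"] == compartment) | (samples["cohort"] == "normal")
    return list(samples.index[mask])


def run_differential(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    compartment: str,
    ranks: pd.DataFrame | None = None,
    per_pair_ranks: bool = False,
    low_power_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All (tumor group x normal tissue) comparisons and per-exon composites.

    Percentile ranks are computed once over the compartment's population
    (tumor groups of the compartment plus all normal samples) and reused
    for the weights; ``per_pair_ranks=True`` recomputes them within each
    pair instead.
    """
    tumor_groups = sorted(
        samples.loc[(samples["cohort"] == "tumor") & (samples["compartment"] == compartment), "group"].unique()
    )
    tissues = sorted(samples.loc[samples["cohort"] == "normal", "group"].unique())
    if not tumor_groups:
        raise ValueError(f"no tumor groups in compartment {compartment!r}")

    comp_cols = compartment_samples(samples, compartment)
    if ranks is None:
        ranks = percentile_ranks(expr, comp_cols)

    cols_of = {g: list(samples.index[samples["group"] == g]) for g in tumor_groups + tissues}
    exon_ids = expr.index

    pair_rows = []
    z_cols = []
    w_cols = []
    for g in tumor_groups:
        X = expr[cols_of[g]].to_numpy()
        n1 = X.shape[1]
        for t in tissues:
            Y = expr[cols_of[t]].to_numpy()
            n2 = Y.shape[1]
            U = u_matrix(X, Y)
            z = z_from_u(U, n1, n2)
            if per_pair_ranks:
                pr = percentile_ranks(expr, cols_of[g] + cols_of[t])
                w = (np.median(pr[cols_of[g]].to_numpy(), axis=1)
                     - np.median(pr[cols_of[t]].to_numpy(), axis=1))
            else:
                w = (np.median(ranks[cols_of[g]].to_numpy(), axis=1)
                     - np.median(ranks[cols_of[t]].to_numpy(), axis=1))
            z_cols.append(z)
            w_cols.append(w)
            pair_rows.append(pd.DataFrame({
                "exon_id": exon_ids,
                "tumor_group": g,
                "normal_group": t,
                "n1": n1,
                "n2": n2,
                "U": U,
                "z": z,
                "w": w,
                "low_power": (n1 < low_power_n) or (n2 < low_power_n),
            }))

    Z = np.column_stack(z_cols)  # exon x k
    W = np.column_stack(w_cols)
    denom = np.sqrt((W ** 2).sum(axis=1))
    degenerate = denom == 0
    comp = np.where(degenerate, 0.0, (W * Z).sum(axis=1) / np.where(degenerate, 1.0, denom))

    pairs = pd.concat(pair_rows, ignore_index=True)
    composites = pd.DataFrame({
        "exon_id": exon_ids,
        "compartment": compartment,
        "k": Z.shape[1],
        "composite_z": comp,
        "degenerate": degenerate,
    }).reset_index(drop=True)
    return pairs, composites
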