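"""Era-stratified comparison of diagnosis-to-transplant times.

Mismatched-donor transplants historically waited longer because the search
for an acceptable donor took longer; the gap narrowed as registries grew.
The comparison groups times between well-matched (10/10) and mismatched
(<10/10) pairs within each transplant era using a Kruskal-Wallis omnibus
test over all era x matching groups followed by Dunn's post hoc z tests on
the pooled ranks, with mid-ranks and tie-corrected variance.

The adjusted comparison family defaults to the four within-era contrasts
(the only contrasts of scientific interest here); the classical Dunn
adjustment multiplies each p by the family size (Bonferroni), other methods
from :func:`statsmodels.stats.multitest.multipletests` may be requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hlamatch.pair_matching import ERAS


@dataclass
class GroupComparisonResult:
    """Omnibus and pairwise results of the time-to-transplant comparison."""

    group_stats: pd.DataFrame  # era x status: n, median, q1, q3
    statistic: float  # Kruskal-Wallis H (tie corrected)
    pvalue: float
    contrasts: pd.DataFrame  # one row per contrast: z, p, p_adj, significant
    alpha: float = 0.01


def dunn_z(
    values: np.ndarray, groups: np.ndarray, group_a, group_b
) -> float:
    """Dunn's z statistic for one pairwise contrast on pooled mid-ranks.

    ``z = (mean_rank_a - mean_rank_b) / sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b))``
    with the tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tied
    groups of size ``t``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    n_total = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    mask_a = groups == group_a
    mask_b = groups == group_b
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        return float("nan")
    mean_a = ranks[mask_a].mean()
    mean_b = ranks[mask_b].mean()
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / n_a + 1.0 / n_b)
    return float((mean_a - mean_b) / np.sqrt(var))


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(pvals * len(pvals), 1.0)
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method=method)[1]


def compare_time_to_transplant(
    annotations: pd.DataFrame,
    alpha: float = 0.01,
    adjust: str = "bonferroni",
    family: str = "within-era",
) -> GroupComparisonResult:
    """Compare diagnosis-to-transplant time by matching status across eras.

    Parameters
    ----------
    annotations:
        Per-pair table with columns ``era``, ``category`` (or ``grade10``)
        and ``months_dx_to_tx``; missing times are dropped.
    alpha:
        Significance threshold for the adjusted p values (default 0.01).
    adjust:
        Multiplicity adjustment; ``"bonferroni"`` reproduces the classical
        Dunn procedure, any other value is passed to statsmodels'
        ``multipletests``.
    family:
        ``"within-era"`` adjusts over the four 10/10 vs <10/10 within-era
        contrasts; ``"all-pairs"`` over all pairwise group contrasts.

    Raises
    ------
    ValueError
        With fewer than two non-empty groups.
    """
    df = annotations.copy()
    if "category" in df.columns:
        df["status"] = np.where(df["category"] == "10/10", "10/10", "<10/10")
    elif "grade10" in df.columns:
        df["status"] = np.where(df["grade10"] == 10, "10/10", "<10/10")
    else:
        raise ValueError("annotations need a 'category' or 'grade10' column")
    df = df.dropna(subset=["months_dx_to_tx"])
    df = df[df["era"].isin(ERAS)]
    df["group"] = df["era"].astype(str) + "|" + df["status"]

    stats_rows = []
    samples = {}
    for era in ERAS:
        for status in ("10/10", "<10/10"):
            vals = df.loc[
                (df["era"] == era) & (df["status"] == status), "months_dx_to_tx"
            ].to_numpy(dtype=float)
            samples[(era, status)] = vals
            stats_rows.append(
                {
                    "era": era,
                    "status": status,
                    "n": len(vals),
                    "median": float(np.median(vals)) if len(vals) else float("nan"),
                    "q1": float(np.percentile(vals, 25)) if len(vals) else float("nan"),
                    "q3": float(np.percentile(vals, 75)) if len(vals) else float("nan"),
                }
            )
    group_stats = pd.DataFrame(stats_rows).set_index(["era", "status"])

    non_empty = [v for v in samples.values() if len(v) > 0]
    if len(non_empty) < 2:
        raise ValueError("need at least two non-empty groups")
    h_stat, h_p = stats.kruskal(*non_empty)

    pooled = df["months_dx_to_tx"].to_numpy(dtype=float)
    groups = df["group"].to_numpy()

    if family == "within-era":
        contrast_pairs = [
            ((era, "<10/10"), (era, "10/10")) for era in ERAS
        ]
    elif family == "all-pairs":
        keys = [k for k, v in samples.items() if len(v)]
        contrast_pairs = [
            (keys[i], keys[j])
            for i in range(len(keys))
            for j in range(i + 1, len(keys))
        ]
    else:
        raise ValueError(f"unknown family {family!r}")

    rows = []
    for (era_a, st_a), (era_b, st_b) in contrast_pairs:
        ga = f"{era_a}|{st_a}"
        gb = f"{era_b}|{st_b}"
        if len(samples[(era_a, st_a)]) == 0 or len(samples[(era_b, st_b)]) == 0:
            rows.append(
                {
                    "contrast": f"{ga} vs {gb}",
                    "z": float("nan"),
                    "p": float("nan"),
                }
            )
            continue
        z = dunn_z(pooled, groups, ga, gb)
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"contrast": f"{ga} vs {gb}", "z": z, "p": p})
    contrasts = pd.DataFrame(rows)
    defined = contrasts["p"].notna()
    p_adj = np.full(len(contrasts), np.nan)
    if defined.any():
        p_adj[defined.to_numpy()] = _adjust(
            contrasts.loc[defined, "p"].to_numpy(), adjust
        )
    contrasts["p_adj"] = p_adj
    contrasts["significant"] = contrasts["p_adj"] < alpha
    return GroupComparisonResult(
        group_stats=group_stats,
        statistic=float(h_stat),
        pvalue=float(h_p),
        contrasts=contrasts,
        alpha=alpha,
    )
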