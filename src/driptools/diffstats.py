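"""Per-gene differential R-loop statistics and group permutation tests.

The differential call compares normalized DRIP signal between BRCA1
mutation carriers (B1) and non-carriers (NC) within one sorted cell type,
gene by gene and region class by region class. The test is directional
(alternative: B1 > NC): a one-sided Welch t-test on the per-sample
normalized values, except for gene-body regions shorter than 2 kb where a
one-sided Wilcoxon rank-sum test is used instead. P values are
Benjamini–Hochberg adjusted within each region class, and a gene is called
differential when log2FC ≥ 0.8 and adjusted P ≤ 0.05 (both inclusive).

The group-level permutation test (used for cell-type-wide comparisons)
regroups the pooled per-sample values into pseudo-NC/B1 splits; it
enumerates all C(n1+n2, n1) regroupings exactly whenever that count is
manageable and falls back to Monte Carlo otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default thresholds of the differential-call rule
FC_CUTOFF = 0.8
PADJ_CUTOFF = 0.05
#: pseudocount (normalized units) added to both group means before the ratio
PSEUDOCOUNT = 0.5
#: gene-body regions shorter than this use the rank-sum test
BODY_RANKSUM_BELOW = 2000
#: exhaustive permutation enumeration cap
EXHAUSTIVE_MAX = 10_000
#: rank-sum exact-enumeration cap; covers all designs up to 8 vs 8
#: (C(16,8) = 12,870 regroupings)
RANKSUM_EXACT_MAX = 20_000


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment; empty in → empty out."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ranksum_greater(a: np.ndarray, b: np.ndarray, exact_max: int = RANKSUM_EXACT_MAX) -> float:
    """One-sided Wilcoxon rank-sum P(a stochastically greater than b).

    When C(n1+n2, n1) ≤ ``exact_max`` the p value is computed by exact
    enumeration of group assignments over the pooled midranks (so ties are
    handled exactly); otherwise scipy's tie-corrected normal approximation
    with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise ValueError("both samples must be nonempty")
    if comb(na + nb, na) <= exact_max:
        ranks = stats.rankdata(np.concatenate([a, b]))
        observed = ranks[:na].sum()
        eps = 1e-9
        hits = 0
        total = 0
        for idx in combinations(range(na + nb), na):
            total += 1
            if ranks[list(idx)].sum() >= observed - eps:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue)


@dataclass
class PermutationResult:
    observed_stat: float
    n_permutations: int
    exhaustive: bool
    p_value: float


def permutation_group_test(
    values_nc: np.ndarray,
    values_b1: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """One-sided permutation test that mean(B1) exceeds mean(NC).

    The statistic is mean(B1) − mean(NC). All C(n1+n2, n1) regroupings are
    enumerated when that count is ≤ 10,000 (the identity regrouping is
    included, so the exhaustive p is never 0); otherwise ``n_perm`` Monte
    Carlo regroupings are drawn and p = (1 + #{perm ≥ obs}) / (1 + n_perm).
    """
    nc = np.asarray(values_nc, dtype=float)
    b1 = np.asarray(values_b1, dtype=float)
    if nc.size < 1 or b1.size < 1:
        raise ValueError("each group needs at least one value")
    observed = float(b1.mean() - nc.mean())
    pooled = np.concatenate([nc, b1])
    n1, n2 = nc.size, b1.size
    total = comb(n1 + n2, n2)
    # tolerance guards against float jitter when a permutation reproduces
    # the observed grouping with a different summation order
    eps = 1e-9 * (1.0 + abs(observed))
    if total <= EXHAUSTIVE_MAX:
        s_all = pooled.sum()
        hits = 0
        for idx in combinations(range(n1 + n2), n2):
            s_b1 = pooled[list(idx)].sum()
            stat = s_b1 / n2 - (s_all - s_b1) / n1
            if stat >= observed - eps:
                hits += 1
        return PermutationResult(observed, total, True, hits / total)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[n1:].mean() - perm[:n1].mean()
        if stat >= observed - eps:
            hits += 1
    return PermutationResult(observed, n_perm, False, (1 + hits) / (1 + n_perm))


def differential_rloop(
    counts: pd.DataFrame,
    cell_type: str | None = None,
    fc_cutoff: float = FC_CUTOFF,
    padj_cutoff: float = PADJ_CUTOFF,
    pseudocount: float = PSEUDOCOUNT,
    body_ranksum_below: int = BODY_RANKSUM_BELOW,
) -> pd.DataFrame:
    """Differential R-loop record per gene × region class (B1 vs NC).

    ``counts`` is a long-format count table (see quantify.COUNT_COLUMNS);
    desert background regions are excluded. Returns one row per gene and
    region class with mean_NC, mean_B1, log2FC, p_value, p_adj, test_used
    and the boolean ``call``. If either group has fewer than two samples
    the p values are undefined (NaN) and no calls are made.
    """
    df = counts[counts["region_class"] != "desert"]
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    if df.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "region_class", "region_length", "mean_NC", "mean_B1",
                "log2FC", "p_value", "p_adj", "test_used", "call",
            ]
        )
    sample_group = df[["sample_id", "group"]].drop_duplicates().set_index("sample_id")["group"]
    piv = df.pivot_table(
        index=["region_id", "region_class", "region_length"],
        columns="sample_id",
        values="normalized",
    )
    nc_cols = [s for s in piv.columns if sample_group[s] == "NC"]
    b1_cols = [s for s in piv.columns if sample_group[s] == "B1"]
    nc = piv[nc_cols].to_numpy(dtype=float)
    b1 = piv[b1_cols].to_numpy(dtype=float)
    mean_nc = nc.mean(axis=1)
    mean_b1 = b1.mean(axis=1)
    log2fc = np.log2((mean_b1 + pseudocount) / (mean_nc + pseudocount))

    idx = piv.index.to_frame(index=False)
    use_ranksum = (
        (idx["region_class"] == "body") & (idx["region_length"] < body_ranksum_below)
    ).to_numpy()

    p = np.full(len(piv), np.nan)
    enough = len(nc_cols) >= 2 and len(b1_cols) >= 2
    if enough:
        t_rows = ~use_ranksum
        if t_rows.any():
            res = stats.ttest_ind(
                b1[t_rows], nc[t_rows], axis=1, equal_var=False, alternative="greater"
            )
            pt = np.asarray(res.pvalue, dtype=float)
            # zero-variance identical groups give NaN (0/0 t); no evidence → p = 1
            pt = np.where(np.isnan(pt), 1.0, pt)
            p[t_rows] = np.clip(pt, np.nextafter(0, 1), 1.0)
        if use_ranksum.any():
            rs_rows = np.flatnonzero(use_ranksum)
            p[rs_rows] = [ranksum_greater(b1[i], nc[i]) for i in rs_rows]
            p[rs_rows] = np.clip(p[rs_rows], np.nextafter(0, 1), 1.0)

    out = pd.DataFrame(
        {
            "gene_id": idx["region_id"],
            "region_class": idx["region_class"],
            "region_length": idx["region_length"],
            "mean_NC": mean_nc,
            "mean_B1": mean_b1,
            "log2FC": log2fc,
            "p_value": p,
            "test_used": np.where(use_ranksum, "signed_ranksum", "signed_t"),
        }
    )
    # BH within each region-class family, mirroring per-region reporting
    out["p_adj"] = np.nan
    if enough:
        for rc, sub_idx in out.groupby("region_class").groups.items():
            sub_p = out.loc[sub_idx, "p_value"].to_numpy()
            out.loc[sub_idx, "p_adj"] = bh_adjust(sub_p)
    out["call"] = (
        (out["log2FC"] >= fc_cutoff) & (out["p_adj"] <= padj_cutoff)
    ).fillna(False)
    if not enough:
        out["call"] = False
    return out.reset_index(drop=True)
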