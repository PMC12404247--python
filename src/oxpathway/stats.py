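"""Group-level nonparametric statistics and summary-table generation.

Continuous variables are compared across groups with the Kruskal–Wallis test
(tie-corrected H, chi-square reference distribution; an exact permutation p
is reported alongside for very small samples). Post hoc pairwise comparisons
default to two-sided Mann–Whitney rank-sum tests with Bonferroni
multiplication over the number of pairs; Dunn's rank-based z-test is
available behind ``method="dunn"``. Tables report median [p25, p75] using
linear-interpolation percentiles, and n (%) for categoricals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KruskalWallisResult",
    "PairwiseResult",
    "kruskal_wallis",
    "pairwise_posthoc",
    "summary_table",
]

ALPHA = 0.05
#: footnote-letter scheme used in clinical tables for the canonical trio
_CANONICAL_LETTERS = {
    frozenset(("control", "CFS")): "a",
    frozenset(("control", "PASC")): "b",
    frozenset(("CFS", "PASC")): "c",
}
_EXACT_N_MAX = 10


@dataclass(frozen=True)
class KruskalWallisResult:
    h: float
    df: int
    p: float
    p_exact: Optional[float] = None  # exact permutation p, total n <= 10 only


@dataclass(frozen=True)
class PairwiseResult:
    pair: Tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    letter: Optional[str]
    testable: bool


def _h_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H (used for the permutation reference)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def _exact_permutation_p(groups: Sequence[np.ndarray], h_obs: float) -> float:
    """Exact permutation p: enumerate all assignments of the pooled values to
    the group sizes and count H >= observed. Feasible for total n <= 10."""
    pooled = np.concatenate(groups)
    n = pooled.size
    sizes = [g.size for g in groups]
    count = 0
    total = 0
    indices = list(range(n))

    def recurse(remaining: List[int], assigned: List[np.ndarray]) -> None:
        nonlocal count, total
        depth = len(assigned)
        if depth == len(sizes) - 1:
            parts = assigned + [pooled[np.asarray(remaining)]]
            total += 1
            if _h_statistic(parts) >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(remaining, sizes[depth]):
            rest = [i for i in remaining if i not in combo]
            recurse(rest, assigned + [pooled[np.asarray(combo)]])

    recurse(indices, [])
    return count / total


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> KruskalWallisResult:
    """Kruskal–Wallis omnibus test over named groups.

    All-identical data returns H = 0, p = 1 (no rank information) instead of
    raising. For total n <= 10 an exact permutation p is reported alongside
    the chi-square approximation."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    n_total = sum(a.size for a in arrays)
    if n_total < 3:
        raise ValueError("need a total of at least 3 observations")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(h=0.0, df=df, p=1.0, p_exact=1.0 if n_total <= _EXACT_N_MAX else None)
    h, p = sps.kruskal(*arrays)
    p_exact = _exact_permutation_p(arrays, float(h)) if n_total <= _EXACT_N_MAX else None
    return KruskalWallisResult(h=float(h), df=df, p=float(p), p_exact=p_exact)


def pairwise_posthoc(
    groups: Mapping[str, Sequence[float]],
    method: str = "rank_sum",
    alpha: float = ALPHA,
) -> List[PairwiseResult]:
    """Bonferroni-adjusted pairwise comparisons between all group pairs.

    ``method="rank_sum"`` (default): two-sided Mann–Whitney U per pair.
    ``method="dunn"``: Dunn's z-test on pooled ranks with tie correction.
    Adjusted p = min(1, raw·m) with m the number of pairs; a pair containing
    a group of fewer than 2 observations is marked untestable.
    """
    if method not in ("rank_sum", "dunn"):
        raise ValueError(f"unknown post hoc method {method!r}")
    names = list(groups.keys())
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)

    if method == "dunn":
        pooled = np.concatenate([arrays[k] for k in names])
        ranks = sps.rankdata(pooled)
        n = pooled.size
        mean_rank = {}
        start = 0
        for k in names:
            sz = arrays[k].size
            mean_rank[k] = ranks[start : start + sz].mean() if sz else math.nan
            start += sz
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
        var_base = n * (n + 1) / 12.0 - tie_term

    results = []
    for a, b in pairs:
        xa, xb = arrays[a], arrays[b]
        letter = _CANONICAL_LETTERS.get(frozenset((a, b)))
        if xa.size < 2 or xb.size < 2:
            results.append(
                PairwiseResult((a, b), math.nan, math.nan, math.nan, False, letter, False)
            )
            continue
        if np.all(np.concatenate([xa, xb]) == xa[0]):
            stat, p_raw = 0.0, 1.0
        elif method == "rank_sum":
            stat, p_raw = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        else:
            z = (mean_rank[a] - mean_rank[b]) / math.sqrt(
                var_base * (1.0 / xa.size + 1.0 / xb.size)
            )
            stat, p_raw = z, 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, float(p_raw) * m)
        results.append(
            PairwiseResult(
                pair=(a, b), statistic=float(stat), p_raw=float(p_raw),
                p_adjusted=p_adj, significant=p_adj < alpha, letter=letter, testable=True,
            )
        )
    return results


def _fmt(x: float) -> str:
    return f"{x:.3g}"


def summary_table(
    df: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    categorical: Optional[Mapping[str, object]] = None,
    method: str = "rank_sum",
) -> pd.DataFrame:
    """Per-variable, per-group "median [p25, p75]" (linear-interpolation
    percentiles) or "n (%)" for categoricals, with the Kruskal–Wallis omnibus
    p and Bonferroni post hoc significance letters.

    ``categorical`` maps a variable name to the level counted (e.g.
    ``{"sex": "female"}``). Missing variables leave blank, flagged cells.
    """
    if df.empty:
        raise ValueError("empty cohort")
    categorical = dict(categorical or {})
    group_names = list(dict.fromkeys(df[group_col]))
    rows = []
    for var in variables:
        row: Dict[str, object] = {"variable": var}
        if var not in df.columns:
            for g in group_names:
                row[g] = ""
            row["p"] = math.nan
            row["significant_pairs"] = "missing variable"
            rows.append(row)
            continue
        if var in categorical:
            level = categorical[var]
            for g in group_names:
                col = df.loc[df[group_col] == g, var].dropna()
                n_level = int((col == level).sum())
                pct = round(100.0 * n_level / len(col)) if len(col) else 0
                row[g] = f"{n_level} ({pct})"
            row["p"] = math.nan
            row["significant_pairs"] = ""
            rows.append(row)
            continue
        groups = {}
        for g in group_names:
            col = df.loc[df[group_col] == g, var].astype(float).dropna()
            if col.empty:
                row[g] = ""
                continue
            med = float(np.percentile(col, 50))
            p25 = float(np.percentile(col, 25))
            p75 = float(np.percentile(col, 75))
            row[g] = f"{_fmt(med)} [{_fmt(p25)}, {_fmt(p75)}]"
            groups[g] = col.to_numpy()
        if len(groups) >= 2 and all(len(v) > 0 for v in groups.values()):
            kw = kruskal_wallis(groups)
            row["p"] = kw.p
            letters = [
                r.letter or "+".join(r.pair)
                for r in pairwise_posthoc(groups, method=method)
                if r.testable and r.significant
            ]
            row["significant_pairs"] = ",".join(letters)
        else:
            row["p"] = math.nan
            row["significant_pairs"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
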