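"""Rank-based hypothesis tests and descriptive group summaries.

The exact small-sample modes enumerate the full permutation null
distribution (all rank assignments for the rank-sum test, all sign patterns
for the signed-rank test), handling ties by mid-ranks, and report the
two-tailed p as twice the smaller tail probability (capped at 1).  Above a
combined sample size of 20 the tests switch to the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GroupSummary

EXACT_N_MAX = 20


def _tail_p_from_counts(counts: dict[int, float], s_obs: int) -> float:
    """Two-tailed p from an enumerated statistic distribution."""
    total = sum(counts.values())
    p_lo = sum(c for s, c in counts.items() if s <= s_obs) / total
    p_hi = sum(c for s, c in counts.items() if s >= s_obs) / total
    return min(1.0, 2.0 * min(p_lo, p_hi))


def _ranksum_null_counts(ranks2: Sequence[int], n_x: int) -> dict[int, float]:
    """Distribution of (2x) rank sum of an n_x-subset, by dynamic programming.

    ``ranks2`` are mid-ranks doubled so they are integers.  Returns
    {sum: number of subsets}.
    """
    # dp[j] maps achievable doubled rank-sum -> count using j chosen items
    dp: list[dict[int, float]] = [dict() for _ in range(n_x + 1)]
    dp[0][0] = 1.0
    for r in ranks2:
        for j in range(min(n_x, len(dp)) - 1, -1, -1):
            if j + 1 > n_x:
                continue
            for s, c in list(dp[j].items()):
                dp[j + 1][s + r] = dp[j + 1].get(s + r, 0.0) + c
    return dp[n_x]


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode``: "exact" enumerates all rank assignments (mid-rank ties),
    "normal_approx" uses the tie-corrected normal approximation with
    continuity correction, "auto" switches at combined n = 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        mode = "exact" if x.size + y.size <= EXACT_N_MAX else "normal_approx"
    if mode == "normal_approx":
        return float(
            sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    combined = np.concatenate([x, y])
    ranks2 = np.round(2.0 * sps.rankdata(combined)).astype(int)
    s_obs = int(ranks2[: x.size].sum())
    counts = _ranksum_null_counts(ranks2.tolist(), x.size)
    return _tail_p_from_counts(counts, s_obs)


def _signedrank_null_counts(ranks2: Sequence[int]) -> dict[int, float]:
    """Distribution of (2x) positive-rank sum over all sign patterns."""
    counts = {0: 1.0}
    for r in ranks2:
        nxt: dict[int, float] = {}
        for s, c in counts.items():
            nxt[s] = nxt.get(s, 0.0) + c          # negative sign
            nxt[s + r] = nxt.get(s + r, 0.0) + c  # positive sign
        counts = nxt
    return counts


def wilcoxon_signed_rank(
    before: Sequence[float], after: Sequence[float], mode: str = "auto"
) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon convention).  "exact" enumerates
    all 2^n sign patterns; "normal_approx" uses the normal approximation
    with continuity correction; "auto" switches at n = 20 non-zero pairs.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size or before.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    if mode == "auto":
        mode = "exact" if d.size <= EXACT_N_MAX else "normal_approx"
    if mode == "normal_approx":
        return float(
            sps.wilcoxon(
                d, zero_method="wilcox", correction=True, method="approx"
            ).pvalue
        )
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    ranks2 = np.round(2.0 * sps.rankdata(np.abs(d))).astype(int)
    s_obs = int(ranks2[d > 0].sum())
    counts = _signedrank_null_counts(ranks2.tolist())
    return _tail_p_from_counts(counts, s_obs)


def summarize_group(
    values: Sequence[float],
    pathway: Optional[str] = None,
    cell_type: Optional[str] = None,
    layer: Optional[str] = None,
) -> GroupSummary:
    """Descriptive summary with box-plot conventions.

    SD uses the n-1 denominator (blank for n = 1); quartiles use linear
    interpolation between order statistics; whiskers extend to the extreme
    data points lying within 1.5 x IQR of the first/third quartile.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize_group requires n >= 1")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return GroupSummary(
        pathway=pathway,
        cell_type=cell_type,
        layer=layer,
        n=int(v.size),
        mean=float(v.mean()),
        sd=sd,
        sem=sd / np.sqrt(v.size) if sd is not None else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(in_lo.min()),
        whisker_hi=float(in_hi.max()),
    )


def compare_reference_layer(
    cell_table: pd.DataFrame,
    pathway: str,
    cell_type: str = "EXC",
    mode: str = "auto",
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Rank-sum comparisons of the reference layer against every other layer.

    ``cell_table`` must carry columns ``layer``, ``cell_type``,
    ``peak_amp_mV``, ``slope_mV_per_ms``, ``norm_amp``, ``norm_slope``.
    One two-tailed p is computed per (other layer, feature, normalized?)
    combination.  No multiple-comparison adjustment is applied by default;
    ``adjust="bonferroni"`` or ``"holm"`` is available.
    """
    from .types import REFERENCE_LAYER

    ref_layer = REFERENCE_LAYER[pathway]
    df = cell_table[cell_table["cell_type"] == cell_type]
    layers = [
        l for l in df["layer"].dropna().unique().tolist() if l != ref_layer
    ]
    layers.sort()
    feature_cols = {
        ("amplitude", False): "peak_amp_mV",
        ("amplitude", True): "norm_amp",
        ("slope", False): "slope_mV_per_ms",
        ("slope", True): "norm_slope",
    }
    rows = []
    for layer in layers:
        for (feature, normalized), col in feature_cols.items():
            ref_vals = df.loc[df["layer"] == ref_layer, col].dropna().to_numpy()
            other = df.loc[df["layer"] == layer, col].dropna().to_numpy()
            if ref_vals.size == 0 or other.size == 0:
                rows.append(
                    {
                        "layer": layer, "feature": feature,
                        "normalized": normalized, "p": np.nan,
                        "n_ref": int(ref_vals.size), "n_other": int(other.size),
                        "testable": False,
                    }
                )
                continue
            p = wilcoxon_rank_sum(ref_vals, other, mode=mode)
            rows.append(
                {
                    "layer": layer, "feature": feature,
                    "normalized": normalized, "p": p,
                    "n_ref": int(ref_vals.size), "n_other": int(other.size),
                    "testable": True,
                }
            )
    out = pd.DataFrame(rows)
    if adjust is not None and not out.empty:
        mask = out["testable"]
        m = int(mask.sum())
        if adjust == "bonferroni":
            out.loc[mask, "p_adj"] = np.minimum(1.0, out.loc[mask, "p"] * m)
        elif adjust == "holm":
            p = out.loc[mask, "p"].to_numpy()
            order = np.argsort(p)
            adj = np.empty_like(p)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p[idx])
                adj[idx] = min(1.0, running)
            out.loc[mask, "p_adj"] = adj
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    return out
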