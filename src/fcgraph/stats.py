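"""Paired nonparametric comparison of metric tables with multiplicity control.

Pre/post session differences are tested per measure with the two-sided
Wilcoxon signed-rank test: exact permutation p-values (tie-aware, by
dynamic-programming enumeration of the signed-rank distribution) for up
to 25 informative pairs, a normal approximation with tie and continuity
corrections beyond that.  Node-level maps are corrected across nodes
(Benjamini-Hochberg by default, Bonferroni optionally); between-group
contrasts use the unpaired rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p: float
    n_pairs: int  # informative (non-zero) pairs
    method: str  # "exact" | "approx" | "undefined"
    undefined: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided permutation p-value of W+ given the observed midranks.

    Enumerates the distribution of W+ under random signs with a
    convolution over doubled ranks (doubling makes midranks integral).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Incomplete pairs (a non-finite value on either side, e.g. the
    undefined path length of an isolated node) and zero differences are
    dropped; tied absolute differences get midranks.  Exact enumeration
    when <= 25 informative pairs remain, otherwise a normal approximation
    with continuity and tie corrections.  With fewer than 5 informative
    pairs a two-sided p below 0.05 is unreachable and the test is flagged
    undefined rather than scored.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D paired samples of equal length")
    if x.size < 5:
        raise ValueError(f"need >= 5 pairs, got {x.size}")
    complete = np.isfinite(x) & np.isfinite(y)
    d = y[complete] - x[complete]
    d = d[d != 0.0]
    n = d.size
    if n < 5:
        return WilcoxonResult(float("nan"), float("nan"), n, "undefined", True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    dev = w_plus - mu
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "approx")


def mann_whitney_groups(x, y, n_groups: int = 1) -> tuple[float, float]:
    """Two-sided rank-sum test between independent groups.

    Returns the U statistic and the p-value Bonferroni-scaled by
    ``n_groups`` (e.g. 4 when contrasting four task groups).
    """
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(u), float(min(1.0, p * n_groups))


def correct_multiple(p_values, method: str = "bh") -> np.ndarray:
    """Adjusted p-values, monotone and capped at 1 (bh or bonferroni)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    name = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError("method must be 'bh' or 'bonferroni'")
    return multipletests(p, method=name)[1]


def _direction(diffs: np.ndarray) -> str:
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size == 0:
        return "none"
    med = float(np.median(diffs))
    if med > 0:
        return "increase"
    if med < 0:
        return "decrease"
    return "none"


def _check_alignment(pre: pd.DataFrame, post: pd.DataFrame) -> None:
    for col, what in (("subject", "subject identifiers"), ("threshold", "thresholds")):
        a, b = set(pre[col].dropna()), set(post[col].dropna())
        if a != b:
            raise ValueError(f"pre/post {what} differ: {sorted(a ^ b)}")


def compare_sessions(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    scope: str = "global",
    correction: str = "bh",
    pairing: str = "subjects",
) -> pd.DataFrame:
    """Pre-vs-post Wilcoxon comparison of long-format metric tables.

    ``pre``/``post`` are long tables with columns (subject, session,
    threshold, node, measure, value), e.g. concatenated
    :meth:`MetricTable.to_long` outputs pooled over subjects.

    scope="global" tests graph-level values per (measure, threshold);
    with ``pairing="subjects"`` the pairs are subjects, with
    ``pairing="regions"`` the pairs are the per-region group means
    (values averaged over subjects within each session).
    scope="node" tests every (measure, threshold, node) across subjects
    and corrects p-values across nodes within each (measure, threshold).

    Returns one row per test: scope, measure, threshold, node, statistic,
    p_raw, p_corrected, direction, n_pairs, undefined.
    """
    if scope not in ("global", "node"):
        raise ValueError("scope must be 'global' or 'node'")
    if pairing not in ("subjects", "regions"):
        raise ValueError("pairing must be 'subjects' or 'regions'")
    _check_alignment(pre, post)
    rows = []
    if scope == "global":
        a = pre[pre["node"].isna()] if pairing == "subjects" else pre[pre["node"].notna()]
        b = post[post["node"].isna()] if pairing == "subjects" else post[post["node"].notna()]
        key = "subject" if pairing == "subjects" else "node"
        for (measure, thr), ga in a.groupby(["measure", "threshold"], dropna=False):
            gb = b[(b["measure"] == measure) & (b["threshold"] == thr)]
            if pairing == "regions":
                xa = ga.groupby("node")["value"].mean()
                xb = gb.groupby("node")["value"].mean()
            else:
                xa = ga.set_index(key)["value"]
                xb = gb.set_index(key)["value"]
            xa, xb = xa.sort_index(), xb.sort_index()
            if not xa.index.equals(xb.index):
                raise ValueError(f"unmatched {key}s for {measure} at r={thr}")
            res = wilcoxon_signed_rank(xa.to_numpy(), xb.to_numpy())
            rows.append(("global", measure, thr, None, res.statistic, res.p,
                         res.p, _direction(xb.to_numpy() - xa.to_numpy()),
                         res.n_pairs, res.undefined))
        out = pd.DataFrame(rows, columns=_COLUMNS)
        # one family per measure: adjust across its thresholds
        for measure, grp in out.groupby("measure"):
            ok = grp["p_raw"].notna()
            if ok.any():
                out.loc[grp.index[ok], "p_corrected"] = correct_multiple(
                    grp.loc[ok, "p_raw"], correction
                )
        return out

    a = pre[pre["node"].notna()]
    b = post[post["node"].notna()]
    for (measure, thr), ga in a.groupby(["measure", "threshold"], dropna=False):
        gb = b[(b["measure"] == measure) & (b["threshold"] == thr)]
        pa = ga.pivot(index="subject", columns="node", values="value").sort_index()
        pb = gb.pivot(index="subject", columns="node", values="value").sort_index()
        if not (pa.index.equals(pb.index) and pa.columns.equals(pb.columns)):
            raise ValueError(f"unmatched subjects/nodes for {measure} at r={thr}")
        block = []
        for node in pa.columns:
            res = wilcoxon_signed_rank(pa[node].to_numpy(), pb[node].to_numpy())
            block.append(("node", measure, thr, node, res.statistic, res.p,
                          np.nan, _direction(pb[node].to_numpy() - pa[node].to_numpy()),
                          res.n_pairs, res.undefined))
        block = pd.DataFrame(block, columns=_COLUMNS)
        ok = block["p_raw"].notna()
        if ok.any():
            block.loc[ok, "p_corrected"] = correct_multiple(
                block.loc[ok, "p_raw"], correction
            )
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


_COLUMNS = ["scope", "measure", "threshold", "node", "statistic", "p_raw",
            "p_corrected", "direction", "n_pairs", "undefined"]


def consistent_direction(results: pd.DataFrame, measure: str) -> str | None:
    """Direction shared by a measure at every threshold, or None if mixed."""
    d = results[(results["measure"] == measure) & ~results["undefined"]]["direction"]
    vals = set(d)
    return vals.pop() if len(vals) == 1 else None
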