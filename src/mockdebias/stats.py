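"""Distance measures and paired statistics for the bias-reduction evaluation.

Two dissimilarities between closed compositions are used: Bray-Curtis
(half the L1 distance for closed vectors) and the Aitchison distance
(Euclidean distance between centered-log-ratio transforms, after replacing
zeros). Success of a correction is the reduction of the distance to the
DNA-mock or expected composition, tested per stratum with a Wilcoxon
signed-rank test (exact null by enumeration up to n = 25) and optionally
adjusted across strata by Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import replace_zeros


def bray_curtis(x: pd.Series, y: pd.Series) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); in [0, 1] for closed inputs."""
    if not x.index.equals(y.index):
        raise ValueError("mismatched taxa")
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    denom = (xv + yv).sum()
    if denom <= 0:
        raise ValueError("empty compositions")
    return float(np.abs(xv - yv).sum() / denom)


def clr(values: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform of a strictly positive vector."""
    if (values <= 0).any():
        raise ValueError("clr requires strictly positive values")
    logs = np.log(values)
    return logs - logs.mean()


def aitchison(x: pd.Series, y: pd.Series, zero_replace: bool = True) -> float:
    """Aitchison distance: Euclidean distance of clr-transformed compositions.

    Zero relative abundances are replaced (1e-5, the below-detection
    convention) before the transform unless the caller already handled them.
    Scale-invariant: closure constants cancel in the clr.
    """
    if not x.index.equals(y.index):
        raise ValueError("mismatched taxa")
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if zero_replace:
        xv = replace_zeros(xv, "relabund").to_numpy()
        yv = replace_zeros(yv, "relabund").to_numpy()
    return float(np.linalg.norm(clr(xv) - clr(yv)))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) under the exact null, ranks doubled to ints.

    The null distribution of twice the positive-rank sum is built by
    polynomial convolution over the 2^n sign assignments: the generating
    function is the product of (1 + x^r) over the doubled ranks.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    w2 = int(round(w2))
    p_ge = float(dist[w2:].sum())
    p_le = float(dist[: w2 + 1].sum())
    return p_ge, p_le


def wilcoxon_signed_rank(
    before,
    after,
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on differences before - after.

    Zero differences are dropped; ties among |differences| are mid-ranked.
    The statistic is W+, the rank sum of positive differences. For n up to
    ``exact_max_n`` the p-value comes from the exact null distribution
    (enumerated by convolution); beyond that a normal approximation with
    tie correction and continuity correction is used. ``alternative``
    'greater' tests before > after (i.e. a reduction).
    """
    d = np.asarray(before, dtype=float) - np.asarray(after, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero")
    if n < 4:
        raise ValueError(f"need at least 4 nonzero differences, got {n}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        p_ge, p_le = _exact_signed_rank_p(ranks2, w2)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / 48.0
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        p_ge = sps.norm.sf((w_plus - 0.5 - mean) / sd)
        p_le = sps.norm.cdf((w_plus + 0.5 - mean) / sd)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w_plus, float(p)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (FDR)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Spearman correlation with small-sample exact p


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with two-sided p.

    For n <= ``exact_max_n`` the p-value is exact: the permutation null of
    rho is fully enumerated. Larger n use the large-sample approximation.
    A constant input vector has no rank correlation and is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho, p_approx = sps.spearmanr(x, y)
    n = len(x)
    if n > exact_max_n:
        return float(rho), float(p_approx)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        if r >= obs - 1e-12:
            count += 1
        total += 1
    return float(rho), count / total


# ---------------------------------------------------------------------------
# bias-reduction report


@dataclass
class BiasReductionReport:
    per_sample: pd.DataFrame  # sample_id, stratum columns, distance_before/after, metric
    summary: pd.DataFrame  # per stratum medians, reductions, Wilcoxon p


def bias_reduction_report(
    distances: pd.DataFrame,
    strata: list[str],
    alternative: str = "greater",
    adjust: bool = True,
) -> BiasReductionReport:
    """Summarize distance-to-reference before vs after correction per stratum.

    ``distances`` needs columns distance_before, distance_after, and the
    stratifying columns (e.g. protocol, sample_class). Per stratum the
    report gives median before/after, percent reduction of the medians
    (1 - median_after/median_before), the median of per-sample reductions,
    and a one-sided Wilcoxon signed-rank p (omitted below 4 samples); BH
    adjustment is applied across strata.
    """
    rows = []
    for keys, grp in distances.groupby(strata, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        before = grp["distance_before"].to_numpy()
        after = grp["distance_after"].to_numpy()
        med_b = float(np.median(before))
        med_a = float(np.median(after))
        with np.errstate(divide="ignore", invalid="ignore"):
            per_sample_red = 1.0 - np.divide(after, before, out=np.full_like(after, np.nan), where=before > 0)
        row = dict(zip(strata, keys))
        row.update(
            n=len(grp),
            median_before=med_b,
            median_after=med_a,
            pct_reduction_of_medians=(1.0 - med_a / med_b) * 100 if med_b > 0 else np.nan,
            median_pct_reduction=float(np.nanmedian(per_sample_red)) * 100,
        )
        if len(grp) >= 4 and np.any(before != after):
            try:
                _, p = wilcoxon_signed_rank(before, after, alternative=alternative)
            except ValueError:
                p = np.nan
        else:
            p = np.nan
        row["p_wilcoxon"] = p
        rows.append(row)
    summary = pd.DataFrame(rows)
    if adjust and summary["p_wilcoxon"].notna().any():
        mask = summary["p_wilcoxon"].notna()
        summary.loc[mask, "p_adj_bh"] = benjamini_hochberg(summary.loc[mask, "p_wilcoxon"].to_numpy())
    return BiasReductionReport(per_sample=distances.copy(), summary=summary)
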