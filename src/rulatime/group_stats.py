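"""Nonparametric comparison design across workplace conditions.

Within each occupation, the four workplace concepts are compared on the
subject-level rel. av. RST with a Friedman test; when it rejects at
alpha = 0.05 the six pairwise contrasts are evaluated with Conover-Iman
rank-sum t statistics and a Bonferroni-Holm correction within the outcome.
Occupations are compared per workplace concept with Mann-Whitney U tests,
Holm-corrected across the nine outcomes of that concept.

Small-sample p values are exact: the Friedman null distribution is
enumerated over all within-block rank permutations when feasible, and the
Mann-Whitney null over all group labelings for combined n <= 12; both fall
back to the usual tie-corrected asymptotic approximations otherwise.  All
tests are two-sided; a "favored" marker carries the direction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "GroupStatsError",
    "friedman",
    "conover_iman",
    "holm_adjust",
    "mann_whitney_u",
    "compare_dwcs",
    "compare_occupations",
    "significance_stars",
    "ALPHA",
]

ALPHA = 0.05

#: Enumerate the Friedman null exactly when (k!)^n does not exceed this.
_EXACT_FRIEDMAN_LIMIT = 20_000

#: Up to this many subjects, "auto" calibrates the Friedman p by Monte-Carlo
#: permutation (the chi-square reference is conservative for small panels).
_MC_FRIEDMAN_MAX_N = 25

#: Monte-Carlo resamples for the simulated Friedman null (add-one estimator).
_MC_FRIEDMAN_RESAMPLES = 999

#: Enumerate the Mann-Whitney null exactly up to this combined sample size.
_EXACT_MWU_LIMIT = 12


class GroupStatsError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise contrast: statistic, raw and Holm-adjusted p, direction."""

    contrast: str
    statistic: float
    p_raw: float
    p_adj: float
    favored: str  # "first", "second", or "none"
    alpha: float = ALPHA


def _block_ranks(matrix: np.ndarray) -> np.ndarray:
    """Within-subject mid-ranks, one row per subject."""
    return np.apply_along_axis(sps.rankdata, 1, matrix)


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic from a rank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    if a1 - c1 <= 0:  # every row fully tied: no information
        return 0.0
    dev = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    return (k - 1) * dev / (a1 - c1)


def _validate_block_matrix(block_matrix) -> np.ndarray:
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2:
        raise GroupStatsError("block matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if n < 2:
        raise GroupStatsError("need at least 2 subjects")
    if k < 2:
        raise GroupStatsError("need at least 2 conditions")
    if not np.all(np.isfinite(m)):
        raise GroupStatsError("missing or non-finite cell in block matrix")
    return m


def friedman(
    block_matrix,
    method: str = "auto",
    n_resamples: int = _MC_FRIEDMAN_RESAMPLES,
    random_state: int | None = None,
) -> tuple[float, float]:
    """Friedman test across conditions with repeated measures per subject.

    Returns ``(chi2, p)`` where ``chi2`` is the tie-corrected statistic.
    ``method``:

    * ``"exact"`` enumerates all within-block rank permutations (p = share
      of configurations with a statistic at least as large);
    * ``"simulated"`` draws ``n_resamples`` random within-block
      permutations and uses the add-one Monte-Carlo estimator, which is
      valid at any panel size and respects ties;
    * ``"asymptotic"`` uses the chi-square reference with k-1 df (the
      classical test; accurate for large panels, conservative for small);
    * ``"auto"`` picks exact when the enumeration is small enough, then
      simulated up to moderate panel sizes, then asymptotic.

    ``random_state`` seeds the simulated null; the default is a fixed seed
    so results are reproducible without configuration.
    """
    m = _validate_block_matrix(block_matrix)
    n, k = m.shape
    ranks = _block_ranks(m)
    stat = _friedman_statistic(ranks)

    n_config = math.factorial(k) ** n if k <= 10 else math.inf
    if method == "auto":
        if n_config <= _EXACT_FRIEDMAN_LIMIT:
            method = "exact"
        elif n <= _MC_FRIEDMAN_MAX_N:
            method = "simulated"
        else:
            method = "asymptotic"
    if method == "simulated":
        a1 = float((ranks**2).sum())
        c1 = n * k * (k + 1) ** 2 / 4.0
        if a1 - c1 <= 0:
            return stat, 1.0
        rng = np.random.default_rng(1870439423 if random_state is None else random_state)
        keys = rng.random((n_resamples, n, k))
        idx = np.argsort(keys, axis=2)
        permuted = np.take_along_axis(
            np.broadcast_to(ranks, (n_resamples, n, k)), idx, axis=2
        )
        col_sums = permuted.sum(axis=1)
        dev = ((col_sums - n * (k + 1) / 2.0) ** 2).sum(axis=1)
        stats = (k - 1) * dev / (a1 - c1)
        count = int((stats >= stat - 1e-12).sum())
        return stat, (1 + count) / (n_resamples + 1)
    if method == "exact":
        if n_config > 10 * _EXACT_FRIEDMAN_LIMIT:
            raise GroupStatsError("exact Friedman enumeration infeasible at this size")
        perms = list(itertools.permutations(range(k)))
        count = 0
        total = 0
        # permute each block's observed (possibly tied) ranks independently
        for combo in itertools.product(perms, repeat=n):
            permuted = np.array([ranks[i, list(p)] for i, p in enumerate(combo)])
            total += 1
            if _friedman_statistic(permuted) >= stat - 1e-12:
                count += 1
        return stat, count / total
    if method != "asymptotic":
        raise GroupStatsError(f"unknown method {method!r}")
    return stat, float(sps.chi2.sf(stat, k - 1))


def conover_iman(block_matrix, labels: list[str] | None = None) -> list[ComparisonResult]:
    """All pairwise Conover-Iman rank-sum contrasts after a Friedman design.

    The statistic for conditions i, j is
    ``t = (R_i - R_j) / sqrt(2 n (A1 - C1) / ((n-1)(k-1)) * (1 - T1 / (n (k-1))))``
    with ``R`` the rank sums, ``A1`` the sum of squared within-block ranks,
    ``C1 = n k (k+1)^2 / 4`` and ``T1`` the tie-corrected Friedman
    statistic; two-sided p values come from the t distribution with
    ``(n-1)(k-1)`` degrees of freedom.  ``p_adj`` is filled by the callers
    (Holm within a family); here it equals ``p_raw``.
    """
    m = _validate_block_matrix(block_matrix)
    n, k = m.shape
    if (n - 1) * (k - 1) < 1:
        raise GroupStatsError("not enough subjects for Conover-Iman degrees of freedom")
    if labels is None:
        labels = [f"C{j + 1}" for j in range(k)]
    ranks = _block_ranks(m)
    col_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    t1 = _friedman_statistic(ranks)
    df = (n - 1) * (k - 1)
    var = 2.0 * n * (a1 - c1) / df * (1.0 - t1 / (n * (k - 1)))

    results = []
    for i, j in itertools.combinations(range(k), 2):
        diff = col_sums[i] - col_sums[j]
        if var > 0:
            t = diff / np.sqrt(var)
            p = float(2.0 * sps.t.sf(abs(t), df))
        else:
            # degenerate: perfect concordance (or all ties); no variance left
            t = np.inf * np.sign(diff) if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        favored = "none"
        means = m.mean(axis=0)
        if means[i] < means[j]:
            favored = "first"
        elif means[j] < means[i]:
            favored = "second"
        results.append(
            ComparisonResult(
                contrast=f"{labels[i]}-vs-{labels[j]}",
                statistic=float(t),
                p_raw=min(p, 1.0),
                p_adj=min(p, 1.0),
                favored=favored,
            )
        )
    return results


def holm_adjust(p_values) -> list[float]:
    """Bonferroni-Holm step-down adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise GroupStatsError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def _mwu_u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(group_a, group_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_a, p)``.

    Exact p values enumerate all ``C(n_a+n_b, n_a)`` labelings of the pooled
    sample (ties included) when the combined size is at most 12; otherwise a
    normal approximation with tie and continuity corrections is used.  The
    exact two-sided p is ``P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise GroupStatsError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    u_obs = _mwu_u_statistic(a, b)
    mu = n_a * n_b / 2.0

    if method == "auto":
        method = "exact" if n_a + n_b <= _EXACT_MWU_LIMIT else "asymptotic"
    if method == "exact":
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        offset = n_a * (n_a + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total
    if method != "asymptotic":
        raise GroupStatsError(f"unknown method {method!r}")

    pooled = np.concatenate([a, b])
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)  # continuity correction
    z = max(z, 0.0)
    return u_obs, float(2.0 * sps.norm.sf(z))


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def _pivot_blocks(summaries: pd.DataFrame, outcome: str, occupation: str):
    sub = summaries[
        (summaries["outcome"] == outcome) & (summaries["occupation"] == occupation)
    ]
    pivot = sub.pivot_table(
        index="subject_id", columns="dwc", values="rel_av_rst", aggfunc="first"
    )
    pivot = pivot.reindex(columns=[1, 2, 3, 4])
    if pivot.isna().any().any():
        raise GroupStatsError(
            f"missing (subject, DWC) cell for outcome {outcome}, occupation {occupation}"
        )
    return pivot


def compare_dwcs(
    summaries: pd.DataFrame, occupation: str, alpha: float = ALPHA
) -> pd.DataFrame:
    """Friedman-gated Conover-Iman comparison of the four DWCs per outcome.

    ``summaries`` is the tidy per-subject table from
    :func:`rulatime.risk_stats.cohort_summaries`.  Returns one row per
    (outcome, contrast) with the Friedman gate, Conover-Iman statistic, raw
    and Holm-adjusted p (family: the outcome's six contrasts) and the
    favored condition (lower mean rel. av. RST, only when the gate passes
    and p_adj <= alpha).
    """
    rows = []
    outcomes = summaries["outcome"].unique()
    for outcome in outcomes:
        pivot = _pivot_blocks(summaries, outcome, occupation)
        matrix = pivot.to_numpy()
        chi2, p_friedman = friedman(matrix)
        gate = p_friedman <= alpha
        labels = [f"DWC{c}" for c in pivot.columns]
        contrasts = conover_iman(matrix, labels=labels)
        p_adj = holm_adjust([c.p_raw for c in contrasts])
        for c, pa in zip(contrasts, p_adj):
            significant = gate and pa <= alpha
            rows.append(
                {
                    "occupation": occupation,
                    "outcome": outcome,
                    "contrast": c.contrast,
                    "friedman_chi2": chi2,
                    "friedman_p": p_friedman,
                    "statistic": c.statistic,
                    "p_raw": c.p_raw,
                    "p_adj": pa,
                    "significant": significant,
                    "favored": (
                        c.contrast.split("-vs-")[0 if c.favored == "first" else 1]
                        if significant and c.favored != "none"
                        else ""
                    ),
                    "stars": significance_stars(pa) if significant else "",
                }
            )
    return pd.DataFrame(rows)


def compare_occupations(
    summaries: pd.DataFrame, measures: tuple[str, ...] = ("rel_av_rst", "median"),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Mann-Whitney U between occupations per DWC and outcome.

    Holm families are the nine outcomes within one (DWC, measure).  The
    favored occupation (smaller mean of the measure) is reported when the
    adjusted p falls at or below ``alpha``.
    """
    rows = []
    for measure in measures:
        for dwc, sub in summaries.groupby("dwc"):
            family = []
            for outcome, out_sub in sub.groupby("outcome", sort=False):
                a = out_sub.loc[out_sub["occupation"] == "D", measure].to_numpy()
                b = out_sub.loc[out_sub["occupation"] == "DA", measure].to_numpy()
                if a.size == 0 or b.size == 0:
                    raise GroupStatsError(
                        f"need both occupations for DWC {dwc}, outcome {outcome}"
                    )
                u, p = mann_whitney_u(a, b)
                favored = "none"
                if a.mean() < b.mean():
                    favored = "D"
                elif b.mean() < a.mean():
                    favored = "DA"
                family.append((outcome, u, p, favored))
            p_adj = holm_adjust([f[2] for f in family])
            for (outcome, u, p, favored), pa in zip(family, p_adj):
                significant = pa <= alpha
                rows.append(
                    {
                        "dwc": dwc,
                        "measure": measure,
                        "outcome": outcome,
                        "contrast": f"D-vs-DA@DWC{dwc}",
                        "statistic": u,
                        "p_raw": p,
                        "p_adj": pa,
                        "significant": significant,
                        "favored": favored if significant and favored != "none" else "",
                        "stars": significance_stars(pa) if significant else "",
                    }
                )
    return pd.DataFrame(rows)
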