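"""Cohort statistics: pooled-percentile thresholds, ROC threshold
sensitivity, Kruskal-Wallis with Dunn pairwise comparisons, and the
group summary table.

The ROC AUC is the Mann-Whitney probability (ties counted 1/2), which
equals the trapezoid area under the empirical ROC curve; the Gini index is
2 AUC - 1.  The omnibus Kruskal-Wallis p-value uses the chi-square
approximation by default; because that approximation is poor at the tiny
group sizes typical here, a Monte-Carlo permutation p-value is available
via ``p_method="permutation"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np
from scipy.stats import chi2, norm, rankdata

from .errors import DegenerateLabelError, ParameterError, SizeError


# ---------------------------------------------------------------------------
# pooled percentile thresholds

def pooled_percentile_threshold(per_subject_values, tail, pct=1.0,
                                areas=None):
    """Pool face values across subjects and return the tail percentile.

    ``tail="upper"`` returns the (100 - pct) percentile (e.g. the top-1%
    OSI cut), ``tail="lower"`` the pct percentile (e.g. the lowest-1%
    shear-rate cut); linear interpolation between order statistics.  Face
    values are pooled unweighted by default; pass matching ``areas`` for
    the area-weighted variant.
    """
    arrays = [np.asarray(getattr(v, "pooled_values", lambda: v)(), dtype=float)
              if hasattr(v, "pooled_values") else np.asarray(v, dtype=float)
              for v in per_subject_values]
    pooled = np.concatenate([a.ravel() for a in arrays]) if arrays else np.array([])
    if pooled.size == 0:
        raise SizeError("no pooled values")
    if tail not in ("upper", "lower"):
        raise ParameterError("tail must be 'upper' or 'lower'")
    q = 100.0 - pct if tail == "upper" else pct
    if areas is None:
        return float(np.percentile(pooled, q))
    w = np.concatenate([np.asarray(a, dtype=float).ravel() for a in areas])
    if w.shape != pooled.shape:
        raise ParameterError("areas must match pooled values")
    order = np.argsort(pooled)
    x, w = pooled[order], w[order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(q / 100.0, cdf, x))


# ---------------------------------------------------------------------------
# ROC / threshold sweep

@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    gini: float

    @property
    def auc_trapezoid(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC curve with Mann-Whitney AUC (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels must have the same length")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    cuts = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in cuts:
        sel = scores >= c
        tpr.append((sel & labels).sum() / n_pos)
        fpr.append((sel & ~labels).sum() / n_neg)
    return ROCResult(
        thresholds=cuts,
        fpr=np.array(fpr),
        tpr=np.array(tpr),
        auc=float(auc),
        gini=float(2 * auc - 1),
    )


def threshold_sweep(scores_by_candidate, labels):
    """Pick the velocity threshold whose scores separate events best.

    ``scores_by_candidate`` maps candidate threshold (cm/s) to the
    per-subject low-velocity volume scores at that threshold.  Returns
    ``(best_threshold, {candidate: ROCResult})``; ties in AUC go to the
    smallest candidate.
    """
    if not scores_by_candidate:
        raise SizeError("need at least one candidate threshold")
    results = {}
    best, best_auc = None, -np.inf
    for cand in sorted(scores_by_candidate):
        res = roc_curve(scores_by_candidate[cand], labels)
        results[cand] = res
        if res.auc > best_auc + 1e-12:
            best, best_auc = cand, res.auc
    return best, results


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

@dataclass
class GroupComparison:
    group_labels: list
    group_n: list
    group_mean: list
    group_sd: list
    h_statistic: Optional[float] = None
    p_omnibus: Optional[float] = None
    pairwise_p: dict = dfield(default_factory=dict)   # (label_a, label_b) -> adjusted p
    adjust: str = "bonferroni"
    alpha: float = 0.05

    @property
    def significant_pairs(self):
        return {k: p for k, p in self.pairwise_p.items() if p < self.alpha}


def _kw_h(groups):
    """Tie-corrected Kruskal-Wallis H for a list of 1D samples."""
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    h = 0.0
    i = 0
    for n in ns:
        h += ranks[i:i + n].sum() ** 2 / n
        i += n
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, t = np.unique(pooled, return_counts=True)
    corr = 1.0 - (t ** 3 - t).sum() / (N ** 3 - N)
    if corr == 0.0:
        return 0.0    # all observations identical
    return h / corr


def kruskal_wallis_pairwise(groups, labels=None, alpha=0.05,
                            adjust="bonferroni", p_method="chi2",
                            n_permutations=20000, rng=None) -> GroupComparison:
    """Kruskal-Wallis omnibus test with Dunn's pairwise z comparisons.

    Pairwise p-values are two-sided normal probabilities of Dunn's z on
    the pooled ranks, Bonferroni-adjusted by default (``adjust="none"``
    disables the correction).  ``p_method="permutation"`` replaces the
    chi-square omnibus approximation with a Monte-Carlo permutation null.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise SizeError("need >= 2 groups with >= 2 observations each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    pooled = np.concatenate(groups)

    h = _kw_h(groups)
    if np.ptp(pooled) == 0:
        p_omni = 1.0
    elif p_method == "chi2":
        p_omni = float(chi2.sf(h, k - 1))
    elif p_method == "permutation":
        rng = np.random.default_rng(rng)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            splits = np.split(perm, np.cumsum(ns)[:-1])
            if _kw_h(splits) >= h - 1e-12:
                count += 1
        p_omni = (count + 1) / (n_permutations + 1)
    else:
        raise ParameterError(f"unknown p_method {p_method!r}")

    ranks = rankdata(pooled)
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (12.0 * (N - 1))
    var0 = N * (N + 1) / 12.0 - tie_term
    rbar = []
    i = 0
    for n in ns:
        rbar.append(ranks[i:i + n].mean())
        i += n
    m = k * (k - 1) / 2
    pairwise = {}
    for a in range(k):
        for b in range(a + 1, k):
            if var0 <= 0:
                p = 1.0
            else:
                z = (rbar[a] - rbar[b]) / np.sqrt(var0 * (1 / ns[a] + 1 / ns[b]))
                p = 2.0 * norm.sf(abs(z))
                if adjust == "bonferroni":
                    p = min(1.0, p * m)
                elif adjust != "none":
                    raise ParameterError(f"unknown adjust {adjust!r}")
            pairwise[(labels[a], labels[b])] = float(p)

    return GroupComparison(
        group_labels=list(labels),
        group_n=[int(n) for n in ns],
        group_mean=[float(g.mean()) for g in groups],
        group_sd=[float(g.std(ddof=1)) for g in groups],
        h_statistic=float(h),
        p_omnibus=float(p_omni),
        pairwise_p=pairwise,
        adjust=adjust,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# group summary (Table-2-shaped)

METRIC_NAMES = (
    "low_shear_area_pct",
    "high_osi_area_pct",
    "low_velocity_volume_pct",
    "stasis_pct",
)


def group_summary_table(summaries, metrics=METRIC_NAMES, alpha=0.05,
                        adjust="bonferroni"):
    """Per-metric group comparison plus the full-cycle stasis count.

    Returns ``(comparisons, stasis_full_counts)``: a dict mapping metric
    name to a GroupComparison (pairwise p-values omitted when only one
    group is present), and per-group counts of subjects whose stasis spans
    the entire cardiac cycle (stasis_pct == 100).
    """
    if not summaries:
        raise SizeError("no subject summaries")
    present = []
    for s in summaries:
        if s.group_label not in present:
            present.append(s.group_label)
    comparisons = {}
    for metric in metrics:
        groups, labels = [], []
        for g in present:
            vals = [getattr(s, metric) for s in summaries
                    if s.group_label == g and getattr(s, metric) is not None]
            if vals:
                groups.append(np.array(vals, dtype=float))
                labels.append(g)
        if not groups:
            continue
        if len(groups) == 1 or any(len(g) < 2 for g in groups):
            comparisons[metric] = GroupComparison(
                group_labels=labels,
                group_n=[len(g) for g in groups],
                group_mean=[float(g.mean()) for g in groups],
                group_sd=[float(g.std(ddof=1)) if len(g) > 1 else 0.0 for g in groups],
            )
        else:
            comparisons[metric] = kruskal_wallis_pairwise(
                groups, labels=labels, alpha=alpha, adjust=adjust
            )
    stasis_full = {
        g: sum(
            1 for s in summaries
            if s.group_label == g and s.stasis_pct is not None
            and s.stasis_pct >= 100.0 - 1e-9
        )
        for g in present
    }
    return comparisons, stasis_full


def comparisons_to_frame(comparisons, stasis_full=None):
    """Flatten group comparisons into a tidy Table-2-style DataFrame."""
    import pandas as pd

    rows = []
    for metric, comp in comparisons.items():
        row = {"metric": metric}
        for lab, n, mu, sd in zip(comp.group_labels, comp.group_n,
                                  comp.group_mean, comp.group_sd):
            row[f"{lab}_n"] = n
            row[f"{lab}_mean"] = mu
            row[f"{lab}_sd"] = sd
        for (a, b), p in comp.pairwise_p.items():
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    if stasis_full is not None:
        row = {"metric": "stasis_full_cycle_count"}
        for g, c in stasis_full.items():
            row[f"{g}_mean"] = c
        rows.append(row)
    return pd.DataFrame(rows)
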