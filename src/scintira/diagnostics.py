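"""Diagnostic-test evaluation: ROC/AUC, Youden cut-offs, predictive values,
group comparisons and correlations.

Conventions follow standard diagnostic-test methodology for an uptake
biomarker where *higher* scores indicate disease:

* decision rule "score >= cutoff -> positive";
* the empirical ROC is traced over the unique observed scores, and the
  trapezoidal AUC equals the tie-corrected Mann-Whitney statistic
  (ties count 1/2);
* AUC confidence intervals by class-stratified percentile bootstrap;
* binomial proportions carry exact Clopper-Pearson intervals;
* group location comparisons are gated on Levene's test: homogeneous
  variances -> one-way ANOVA with Scheffe post-hoc, otherwise
  Kruskal-Wallis with Dunn post-hoc;
* Pearson correlations with Fisher-z confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import AnalysisError


# ------------------------------------------------------------------ ROC


@dataclass
class ROCCurve:
    """Empirical ROC: thresholds with aligned sensitivity/specificity."""

    thresholds: np.ndarray  # descending unique scores, +inf sentinel first
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> ROCCurve:
    """Empirical ROC over unique-score cutoffs (rule: score >= cutoff).

    The AUC is the trapezoid over the (FPR, TPR) polyline, which for this
    construction equals P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise AnalysisError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError("ROC needs at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    sens = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden_cutoff(roc: ROCCurve) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing J = sens + spec - 1.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold.  The +inf sentinel (nothing positive) is never selected
    unless it is the unique maximum.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, j.size):
        if (
            j[i] > j[best] + 1e-12
            or (abs(j[i] - j[best]) <= 1e-12 and roc.sensitivity[i] > roc.sensitivity[best])
            or (
                abs(j[i] - j[best]) <= 1e-12
                and roc.sensitivity[i] == roc.sensitivity[best]
                and roc.thresholds[i] < roc.thresholds[best]
            )
        ):
            best = i
    return (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )


def bootstrap_auc_ci(scores, labels, B: int = 2000, alpha: float = 0.05,
                     seed: int = 0) -> tuple[float, float]:
    """Class-stratified percentile bootstrap interval for the AUC."""
    if B < 100:
        raise AnalysisError(f"bootstrap needs B >= 100, got {B}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise AnalysisError("bootstrap needs both classes present")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB00]))
    aucs = np.empty(B)
    for b in range(B):
        while True:
            ps = rng.choice(pos, size=pos.size, replace=True)
            ns = rng.choice(neg, size=neg.size, replace=True)
            # stratified resampling keeps both classes; the redraw guard is
            # kept for custom subclassed samplers
            if ps.size and ns.size:
                break
        aucs[b] = _mann_whitney_auc(ps, ns)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Tie-corrected pair-probability AUC via midranks (O(n log n))."""
    ranks = stats.rankdata(np.r_[pos, neg])
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


# ------------------------------------------------------- confusion metrics


@dataclass
class ProportionWithCI:
    value: float | None
    ci: tuple[float, float] | None
    numerator: int
    denominator: int


@dataclass
class DiagnosticSummary:
    """Confusion counts with sens/spec/PPV/NPV (Clopper-Pearson CIs)."""

    cutoff: float | None
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: ProportionWithCI
    specificity: ProportionWithCI
    ppv: ProportionWithCI
    npv: ProportionWithCI
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None


def _proportion(num: int, den: int, alpha: float) -> ProportionWithCI:
    if den == 0:
        return ProportionWithCI(value=None, ci=None, numerator=num, denominator=0)
    lo, hi = proportion_confint(num, den, alpha=alpha, method="beta")
    return ProportionWithCI(
        value=num / den, ci=(float(lo), float(hi)), numerator=num, denominator=den
    )


def confusion_metrics(tp: int, fp: int, fn: int, tn: int,
                      alpha: float = 0.05, cutoff: float | None = None) -> DiagnosticSummary:
    """Sens/spec/PPV/NPV with exact binomial CIs from confusion counts.

    Empty PPV/NPV denominators are reported as undefined (value None),
    never as zero.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise AnalysisError(f"count {name} must be >= 0, got {v}")
    if tp + fn < 1:
        raise AnalysisError("need at least one positive (tp + fn >= 1)")
    if tn + fp < 1:
        raise AnalysisError("need at least one negative (tn + fp >= 1)")
    return DiagnosticSummary(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_proportion(tp, tp + fn, alpha),
        specificity=_proportion(tn, tn + fp, alpha),
        ppv=_proportion(tp, tp + fp, alpha),
        npv=_proportion(tn, tn + fn, alpha),
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def predictive_values_from_rates(sensitivity: float, specificity: float,
                                 n_pos: int, n_neg: int) -> tuple[float | None, float | None]:
    """PPV and NPV reconstructed from published sens/spec and class sizes.

    Counts are recovered by rounding sens*n_pos and spec*n_neg to the
    nearest integer (half away from zero); predictive values follow from
    the implied confusion matrix.  Undefined values (empty denominator)
    are returned as None.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise AnalysisError("rates must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise AnalysisError("class sizes must be >= 1")
    tp = _round_half_away(sensitivity * n_pos)
    tn = _round_half_away(specificity * n_neg)
    fp = n_neg - tn
    fn = n_pos - tp
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    return ppv, npv


def evaluate_marker(scores, labels, B: int = 2000, alpha: float = 0.05,
                    seed: int = 0) -> DiagnosticSummary:
    """Full marker evaluation: ROC, Youden cut-off, confusion metrics, AUC CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    roc = roc_auc(scores, labels)
    cutoff, _, _ = youden_cutoff(roc)
    pred = scores >= cutoff
    summary = confusion_metrics(
        tp=int((pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
        tn=int((~pred & ~labels).sum()),
        alpha=alpha,
        cutoff=float(cutoff),
    )
    summary.auc = roc.auc
    summary.auc_ci = bootstrap_auc_ci(scores, labels, B=B, alpha=alpha, seed=seed)
    return summary


# ------------------------------------------------------- group comparisons


@dataclass
class GroupComparisonResult:
    test_used: str  # "anova_scheffe" | "kruskal_dunn"
    levene_p: float
    global_p: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def _scheffe_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    names = list(groups)
    k = len(names)
    n_total = sum(g.size for g in groups.values())
    grand = np.concatenate(list(groups.values()))
    df_w = n_total - k
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    msw = ssw / df_w
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            f = (a.mean() - b.mean()) ** 2 / (msw * (1 / a.size + 1 / b.size))
            out[(names[i], names[j])] = float(stats.f.sf(f / (k - 1), k - 1, df_w))
    del grand
    return out


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    names = list(groups)
    sizes = {n: groups[n].size for n in names}
    pooled = np.concatenate([groups[n] for n in names])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name in names:
        stop = start + sizes[name]
        mean_ranks[name] = ranks[start:stop].mean()
        start = stop
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            out[(a, b)] = float(2.0 * stats.norm.sf(abs(z)))
    return out


def compare_groups(groups: dict, alpha_levene: float = 0.05) -> GroupComparisonResult:
    """Levene-gated location comparison of 2+ groups.

    Homogeneous variances (Levene p >= alpha) -> one-way ANOVA with
    Scheffe post-hoc; otherwise Kruskal-Wallis with Dunn post-hoc
    (unadjusted two-sided pairwise p-values).
    """
    groups = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise AnalysisError("compare_groups needs at least 2 groups")
    for name, g in groups.items():
        if g.size < 3:
            raise AnalysisError(f"group {name!r} has fewer than 3 values")
    values = list(groups.values())
    levene_p = float(stats.levene(*values).pvalue)
    if levene_p >= alpha_levene:
        global_p = float(stats.f_oneway(*values).pvalue)
        return GroupComparisonResult(
            test_used="anova_scheffe",
            levene_p=levene_p,
            global_p=global_p,
            pairwise=_scheffe_pairwise(groups),
        )
    global_p = float(stats.kruskal(*values).pvalue)
    return GroupComparisonResult(
        test_used="kruskal_dunn",
        levene_p=levene_p,
        global_p=global_p,
        pairwise=_dunn_pairwise(groups),
    )


# ------------------------------------------------------------ correlation


@dataclass
class CorrelationResult:
    r: float
    ci: tuple[float, float]
    p: float
    n: int


def pearson_correlation(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with two-sided p and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise AnalysisError("correlation needs matched samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AnalysisError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = x.size
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=r, ci=ci, p=float(res.pvalue), n=n)


# ----------------------------------------------------- moment simulations


def simulate_group_auc(pos_groups, neg_groups, n_seeds: int = 50,
                       seed: int = 0, floor: float = 0.05) -> float:
    """Mean empirical AUC over seeds for group moments.

    ``pos_groups`` / ``neg_groups`` are sequences of ``(n, mean, sd)``;
    per seed every group is drawn from its truncated normal (lower bound
    ``floor``) and the pooled positives are scored against the pooled
    negatives.
    """
    from .cohort import truncated_normal

    root = np.random.SeedSequence([seed, 0xA0C])
    aucs = np.empty(n_seeds)
    for i, child in enumerate(root.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        pos = np.concatenate(
            [truncated_normal(rng, m, s, floor, size=n) for n, m, s in pos_groups]
        )
        neg = np.concatenate(
            [truncated_normal(rng, m, s, floor, size=n) for n, m, s in neg_groups]
        )
        aucs[i] = _mann_whitney_auc(pos, neg)
    return float(aucs.mean())


# ------------------------------------------------------------------ plots


def plot_roc(roc: ROCCurve, path=None, title: str = "ROC curve"):
    """Optional ROC plot export (PNG/SVG by file suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1 - roc.specificity, roc.sensitivity, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title} (AUC = {roc.auc:.3f})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
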