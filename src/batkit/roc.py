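"""Diagnostic discrimination: empirical ROC curve, AUC and optimal cutoff.

Orientation is "higher score = case": for the BAT AC50, allergic subjects
(cases) have higher threshold sensitivity than merely sensitized subjects
(controls).  At a cutoff *c* a subject is called a case when ``score > c``;
sensitivity is the fraction of cases called, specificity the fraction of
controls not called.

The empirical AUC by the trapezoid rule over all distinct-score operating
points equals the Mann-Whitney U statistic (with half-credit for ties)
divided by ``n_cases * n_controls`` — an identity the test-suite checks
against :func:`batkit.stats.mann_whitney` on every input.

The optimal cutoff maximises the Youden index J = sensitivity + specificity
- 1 ("highest specificity and sensitivity"); ties are broken toward higher
specificity, then toward the higher cutoff.  Cutoffs are reported as the
midpoint between adjacent distinct scores (sentinel cutoffs half a unit
outside the score range represent the all-case / no-case ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ROCResult", "roc_curve", "optimal_cutoff", "bootstrap_auc_ci", "plot_roc"]


@dataclass
class ROCResult:
    """Empirical ROC curve with its AUC and Youden-optimal operating point."""

    score_name: str
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    sensitivity_at_optimal: float
    specificity_at_optimal: float
    n_cases: int
    n_controls: int
    notes: list[str] = field(default_factory=list)


def roc_curve(scores, labels, score_name: str = "score") -> ROCResult:
    """Build the empirical ROC curve of a score against binary labels.

    ``labels`` are truthy for cases.  Both classes must be present.  Returns
    operating points for every distinct score plus the two sentinel ends,
    ordered by decreasing cutoff (sensitivity non-decreasing).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels lengths differ")
    n_cases = int(labels.sum())
    n_controls = int(scores.size - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("roc_curve requires both classes present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    distinct = np.r_[True, np.diff(s) != 0]
    boundaries = np.nonzero(np.r_[distinct[1:], True])[0]  # last index per value
    tp = np.cumsum(lab)[boundaries]
    fp = np.cumsum(~lab)[boundaries]
    sens = np.r_[0.0, tp / n_cases]
    fpr = np.r_[0.0, fp / n_controls]
    spec = 1.0 - fpr

    values = s[boundaries]  # distinct scores, descending
    upper = np.r_[values[0] + 1.0, values]
    lower = np.r_[values, values[-1] - 1.0]
    cutoffs = (upper + lower) / 2.0  # midpoints between adjacent distinct scores

    auc = float(np.trapezoid(sens, fpr))
    result = ROCResult(
        score_name=score_name,
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=np.nan,
        sensitivity_at_optimal=np.nan,
        specificity_at_optimal=np.nan,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    cut, se, sp = optimal_cutoff(result)
    result.optimal_cutoff = cut
    result.sensitivity_at_optimal = se
    result.specificity_at_optimal = sp
    return result


def optimal_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Youden-optimal operating point of an ROC curve.

    Maximises J = sensitivity + specificity - 1; ties go to the point with
    higher specificity, then to the higher cutoff.  Returns
    ``(cutoff, sensitivity, specificity)``.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, len(j)):
        if (
            j[i] > j[best] + 1e-12
            or (
                abs(j[i] - j[best]) <= 1e-12
                and (
                    roc.specificity[i] > roc.specificity[best] + 1e-12
                    or (
                        abs(roc.specificity[i] - roc.specificity[best]) <= 1e-12
                        and roc.cutoffs[i] > roc.cutoffs[best]
                    )
                )
            )
        ):
            best = i
    return (
        float(roc.cutoffs[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the AUC (stratified)."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    cases = scores[labels]
    controls = scores[~labels]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(cases, size=cases.size, replace=True)
        ct = rng.choice(controls, size=controls.size, replace=True)
        aucs[b] = roc_curve(
            np.concatenate([cs, ct]),
            np.concatenate([np.ones(cs.size, bool), np.zeros(ct.size, bool)]),
        ).auc
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def plot_roc(roc: ROCResult, path=None, ax=None):
    """Plot the ROC curve (1 - specificity vs sensitivity)."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1.0 - roc.specificity, roc.sensitivity, drawstyle="steps-post",
            label=f"{roc.score_name} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.plot(
        1.0 - roc.specificity_at_optimal,
        roc.sensitivity_at_optimal,
        "o",
        c="crimson",
        label=f"cutoff {roc.optimal_cutoff:.2f}",
    )
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
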