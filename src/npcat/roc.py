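"""ROC construction, concordance statistic, and Youden-index cutoff.

Conventions
-----------
* Positivity: a score **at or above** the threshold is test-positive
  (matching the clinical rule "SUVmax ≥ cutoff").
* Candidate thresholds are the unique observed scores, so the selected
  cutoff is itself an observed value; sentinel end points at ±∞ complete
  the curve.
* The AUC is the Mann–Whitney concordance probability with ties counted
  0.5, so it is exactly the probability that a randomly chosen
  deep-invasion lesion scores higher than a randomly chosen shallow one.
* The AUC confidence interval uses the DeLong analytic variance; when that
  variance is degenerate (e.g. perfect separation) a seeded bootstrap
  (2,000 resamples) is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["RocCurve", "CutoffResult", "roc_points", "c_statistic", "youden_cutoff", "plot_roc"]


@dataclass(frozen=True)
class RocCurve:
    #: (threshold, sensitivity, specificity), thresholds increasing.
    operating_points: tuple[tuple[float, float, float], ...]
    auc: float
    auc_ci: tuple[float, float]

    def to_rows(self) -> list[dict[str, float]]:
        return [
            {"threshold": t, "sensitivity": se, "specificity": sp}
            for t, se, sp in self.operating_points
        ]


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def _validate_groups(scores_deep, scores_shallow) -> tuple[np.ndarray, np.ndarray]:
    deep = np.asarray(scores_deep, dtype=float)
    shallow = np.asarray(scores_shallow, dtype=float)
    if deep.size == 0 or shallow.size == 0:
        raise ValidationError("both score groups must be non-empty")
    if np.isnan(deep).any() or np.isnan(shallow).any():
        raise ValidationError("scores must not contain NaN")
    return deep, shallow


def _auc_mann_whitney(deep: np.ndarray, shallow: np.ndarray) -> float:
    """Concordance probability via midranks; ties count 0.5."""
    m, n = deep.size, shallow.size
    ranks = stats.rankdata(np.concatenate([deep, shallow]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return u / (m * n)


def _delong_variance(deep: np.ndarray, shallow: np.ndarray) -> float:
    """DeLong structural-component variance of the AUC estimate."""
    m, n = deep.size, shallow.size
    # placement of each deep score among shallow scores, and vice versa
    v10 = np.array([(np.sum(d > shallow) + 0.5 * np.sum(d == shallow)) / n for d in deep])
    v01 = np.array([(np.sum(deep > s) + 0.5 * np.sum(deep == s)) / m for s in shallow])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _auc_ci(
    deep: np.ndarray,
    shallow: np.ndarray,
    auc: float,
    level: float = 0.95,
    bootstrap_seed: int = 0,
    n_boot: int = 2000,
) -> tuple[float, float]:
    var = _delong_variance(deep, shallow)
    if var > 0:
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        return (max(0.0, auc - half), min(1.0, auc + half))
    # degenerate variance: percentile bootstrap, stratified by group
    rng = np.random.default_rng(bootstrap_seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        d = rng.choice(deep, size=deep.size, replace=True)
        s = rng.choice(shallow, size=shallow.size, replace=True)
        aucs[i] = _auc_mann_whitney(d, s)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return (min(lo, auc), max(hi, auc))


def _sens_spec_at(
    deep: np.ndarray, shallow: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    sens = (deep[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (shallow[None, :] < thresholds[:, None]).mean(axis=1)
    return sens, spec


def roc_points(
    scores_deep: Sequence[float],
    scores_shallow: Sequence[float],
    bootstrap_seed: int = 0,
) -> RocCurve:
    """Full ROC curve: one operating point per unique observed score plus
    sentinel ends (−∞ → everything positive; +∞ → everything negative)."""
    deep, shallow = _validate_groups(scores_deep, scores_shallow)
    uniq = np.unique(np.concatenate([deep, shallow]))
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    sens, spec = _sens_spec_at(deep, shallow, thresholds)
    auc = _auc_mann_whitney(deep, shallow)
    ci = _auc_ci(deep, shallow, auc, bootstrap_seed=bootstrap_seed)
    points = tuple(zip(thresholds.tolist(), sens.tolist(), spec.tolist()))
    return RocCurve(operating_points=points, auc=float(auc), auc_ci=ci)


def c_statistic(
    scores_deep: Sequence[float],
    scores_shallow: Sequence[float],
    bootstrap_seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Concordance probability (AUC) with 95% CI."""
    deep, shallow = _validate_groups(scores_deep, scores_shallow)
    auc = _auc_mann_whitney(deep, shallow)
    return float(auc), _auc_ci(deep, shallow, auc, bootstrap_seed=bootstrap_seed)


def youden_cutoff(
    scores_deep: Sequence[float],
    scores_shallow: Sequence[float],
    tie_break: Literal["lowest", "highest"] = "lowest",
) -> CutoffResult:
    """Observed-value threshold maximising Youden's J = sens + spec − 1.

    Candidate thresholds are the unique observed scores.  Ties in J are
    broken toward the lowest threshold by default (favouring sensitivity);
    ``tie_break="highest"`` favours specificity instead.
    """
    deep, shallow = _validate_groups(scores_deep, scores_shallow)
    thresholds = np.unique(np.concatenate([deep, shallow]))
    sens, spec = _sens_spec_at(deep, shallow, thresholds)
    j = sens + spec - 1.0
    best = j.max()
    candidates = np.flatnonzero(j >= best - 1e-15)
    idx = candidates[0] if tie_break == "lowest" else candidates[-1]
    return CutoffResult(
        threshold=float(thresholds[idx]),
        youden_j=float(j[idx]),
        sens_at_cutoff=float(sens[idx]),
        spec_at_cutoff=float(spec[idx]),
    )


def plot_roc(curve: RocCurve, path: str, title: str = "ROC for deep invasion") -> None:
    """Write the ROC curve to a vector-graphics file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [1 - sp for _, _, sp in curve.operating_points]
    tpr = [se for _, se, _ in curve.operating_points]
    order = np.argsort(fpr, kind="stable")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(np.asarray(fpr)[order], np.asarray(tpr)[order], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    lo, hi = curve.auc_ci
    ax.set_title(f"{title}\nAUC {curve.auc:.2f} (95% CI {lo:.2f}–{hi:.2f})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
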