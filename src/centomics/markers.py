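"""Differential-genus screening, marker-set intersections, and biomarker
panel evaluation by ridge-stabilized logistic regression + ROC.

The genus screen follows the LEfSe recipe in spirit (Kruskal-Wallis filter
plus an effect-size threshold on a log10 scale) but replaces the original
bootstrap LDA score with a deterministic proxy: log10 of the absolute
between-class difference of mean per-million abundances. For a single
feature with no subclass structure the original LDA score is monotone in
this separation, and determinism makes threshold behavior reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, prevalence_filter, tss_normalize
from .stats import kruskal_wallis


@dataclass
class EffectSizeRecord:
    feature_id: str
    kw_p: float
    lda_like_score: float  # log10 units on the per-million scale
    enriched_group: str
    passes: bool


@dataclass
class MarkerPanel:
    features: list[str]
    coefficients: np.ndarray  # aligned with features
    intercept: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray = field(default_factory=lambda: np.array([]))


def lda_effect_screen(
    table: CohortTable,
    labels,
    lda_min: float,
    prevalence_min: float = 0.10,
    p_max: float = 0.05,
) -> list[EffectSizeRecord]:
    """Two-class differential screen on the per-million scale.

    After the prevalence filter and TSS to 1e6, each feature gets a
    Kruskal-Wallis p and the deterministic effect proxy
    ``log10(max(|mean_1 - mean_2|, 1))``; ``passes`` requires p < p_max and
    proxy >= lda_min.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    for c in classes:
        if (labels == c).sum() < 3:
            raise ValueError(f"class {c!r} has < 3 samples")
    filtered, _ = prevalence_filter(table, prevalence_min)
    norm = tss_normalize(filtered, scale=1e6)
    m1 = labels == classes[0]
    m2 = ~m1
    out = []
    for j, fid in enumerate(norm.feature_ids):
        col = norm.values[:, j]
        kw = kruskal_wallis([col[m1], col[m2]])
        diff = float(col[m1].mean() - col[m2].mean())
        score = float(np.log10(max(abs(diff), 1.0)))
        enriched = classes[0] if diff >= 0 else classes[1]
        out.append(
            EffectSizeRecord(
                feature_id=fid,
                kw_p=kw.p_value,
                lda_like_score=score,
                enriched_group=str(enriched),
                passes=bool(kw.p_value < p_max and score >= lda_min),
            )
        )
    return out


def effect_screen_frame(records: list[EffectSizeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "kw_p": [r.kw_p for r in records],
            "lda_like_score": [r.lda_like_score for r in records],
            "enriched_group": [r.enriched_group for r in records],
            "passes": [r.passes for r in records],
        }
    )


def intersect_sets(
    a: dict[str, str],
    b: dict[str, str],
) -> tuple[set[str], set[str], set[str]]:
    """Intersect two direction-annotated feature sets.

    Returns (shared, consistent, conflicting): features in both sets,
    the subset with concordant direction annotations, and the flagged
    discordant remainder.
    """
    shared = set(a) & set(b)
    consistent = {f for f in shared if a[f] == b[f]}
    return shared, consistent, shared - consistent


def logistic_fit(
    X: np.ndarray,
    y,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Binary logistic regression by IRLS with an L2 penalty on the
    non-intercept coefficients (stabilizes separable panels).

    Returns (coefficients, intercept, fitted probabilities).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if set(np.unique(y).tolist()) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    Xd = np.column_stack([np.ones(n), X])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0  # intercept unpenalized
    beta = np.zeros(p + 1)
    dev_old = np.inf
    for it in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        grad = Xd.T @ (y - mu) - pen * beta
        H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(
                "IRLS failed to solve normal equations; try a larger ridge"
            ) from e
        eta = Xd @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        dev = -2.0 * float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        if abs(dev_old - dev) < tol:
            break
        dev_old = dev
    else:
        raise RuntimeError(
            "logistic IRLS did not converge in "
            f"{max_iter} iterations; try a larger ridge"
        )
    probs = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
    return beta[1:], float(beta[0]), probs


def roc_auc(scores, y) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points over grouped score thresholds and the trapezoid AUC.

    Ties are handled by grouping equal scores into one threshold step, which
    makes the trapezoid AUC equal the Mann-Whitney U statistic / (n1 n2)
    with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s, labels = scores[order], y[order]
    # group tied scores
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp = np.concatenate([[0], np.cumsum(labels == 1)[np.append(boundaries - 1, s.size - 1)]])
    fp = np.concatenate([[0], np.cumsum(labels == 0)[np.append(boundaries - 1, s.size - 1)]])
    tpr = tp / n1
    fpr = fp / n0
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_panel(
    X: np.ndarray,
    y,
    feature_ids: list[str],
    ridge: float = 1e-6,
) -> MarkerPanel:
    """Logistic panel score + resubstitution ROC for a small marker set."""
    coefs, intercept, probs = logistic_fit(X, y, ridge=ridge)
    fpr, tpr, auc = roc_auc(probs, y)
    return MarkerPanel(
        features=list(feature_ids),
        coefficients=coefs,
        intercept=intercept,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        scores=probs,
    )
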