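"""Partial least-squares discriminant analysis (NIPALS) with VIP scoring
and a label-permutation overfitting check.

The model is PLS2 on an autoscaled feature matrix X and a column-centered
one-hot class matrix Y. Components are extracted by the classical NIPALS
inner loop (u -> w -> t -> q -> u) with deterministic start u = first Y
column, followed by deflation of both blocks. Component signs are fixed so
the X-loading of largest magnitude is positive, making scores reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PlsdaModel:
    """Fitted PLS-DA model.

    Attributes
    ----------
    weights : (p, A) X-weights, unit norm per component
    scores : (n, A) X-scores, mutually orthogonal
    loadings : (p, A) X-loadings
    y_loadings : (k, A)
    explained_y : (A,) fraction of Y variance captured per component
    classes : class labels in Y-column order
    feature_ids : feature names aligned with the rows of `weights`
    """

    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    explained_y: np.ndarray
    classes: list
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def r2y_cumulative(self) -> float:
        return float(self.explained_y.sum())


def _one_hot(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs >= 2 classes")
    Y = np.zeros((labels.size, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, classes


def plsda_fit(
    X: np.ndarray,
    labels,
    n_components: int = 2,
    feature_ids: list[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PlsdaModel:
    """Fit NIPALS PLS2 on autoscaled X against centered one-hot labels.

    X must already be column-centered (autoscaling upstream); constant
    columns are rejected because the weight update divides by the column
    norm of the deflated block.
    """
    X = np.array(X, dtype=float)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    col_sd = X.std(axis=0)
    if (col_sd == 0).any():
        j = int(np.flatnonzero(col_sd == 0)[0])
        raise ValueError(f"constant X column {j} must be dropped before fitting")
    Y, classes = _one_hot(labels)
    Y = Y - Y.mean(axis=0)
    ss_y0 = float((Y ** 2).sum())
    Xd, Yd = X.copy(), Y.copy()

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    expl = np.zeros(n_components)

    for a in range(n_components):
        u = Yd[:, 0].copy()
        t_old = None
        for it in range(max_iter):
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise RuntimeError(f"component {a + 1}: X block exhausted")
            w /= norm
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                raise RuntimeError(f"component {a + 1}: degenerate scores")
            q = Yd.T @ t / tt
            u = Yd @ q
            if t_old is not None:
                denom = np.linalg.norm(t)
                if denom > 0 and np.linalg.norm(t - t_old) / denom < tol:
                    break
            t_old = t
        else:
            raise RuntimeError(f"NIPALS did not converge for component {a + 1}")
        tt = float(t @ t)
        pvec = Xd.T @ t / tt
        # sign convention: largest-magnitude loading positive
        jmax = int(np.argmax(np.abs(pvec)))
        if pvec[jmax] < 0:
            w, t, pvec, q = -w, -t, -pvec, -q
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pvec, q
        expl[a] = tt * float(q @ q) / ss_y0

    return PlsdaModel(
        weights=W, scores=T, loadings=P, y_loadings=Q,
        explained_y=expl, classes=classes,
        feature_ids=list(feature_ids) if feature_ids is not None else
        [f"f{j}" for j in range(p)],
    )


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_a SS_a w_aj^2 / sum_a SS_a), SS_a = |q_a|^2 t_a't_a.
    Normalized so that mean(VIP^2) = 1 exactly.
    """
    p = model.weights.shape[0]
    tt = (model.scores ** 2).sum(axis=0)
    qq = (model.y_loadings ** 2).sum(axis=0)
    ss = qq * tt
    total = ss.sum()
    if total <= 0:
        raise ValueError("zero explained sum of squares; model captured nothing")
    vip = np.sqrt(p * (model.weights ** 2 @ ss) / total)
    return pd.Series(vip, index=model.feature_ids, name="vip")


def plsda_permutation_test(
    X: np.ndarray,
    labels,
    n_components: int = 2,
    n_permutations: int = 199,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Overfitting check: permute class labels, refit, compare cumulative R2Y.

    Returns (observed R2Y, p-value, null distribution); p uses the add-one
    permutation convention (1 + #{null >= observed}) / (B + 1).
    """
    if n_permutations < 19:
        raise ValueError("need >= 19 permutations")
    labels = np.asarray(labels)
    observed = plsda_fit(X, labels, n_components).r2y_cumulative()
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = plsda_fit(X, rng.permutation(labels), n_components).r2y_cumulative()
    p = (1.0 + float((null >= observed).sum())) / (n_permutations + 1.0)
    return observed, p, null


def select_by_vip_p(
    vip: pd.Series,
    p_values: pd.Series,
    vip_min: float,
    p_max: float,
) -> pd.DataFrame:
    """Features with VIP > vip_min and p < p_max, sorted by VIP descending
    (ties broken by feature id)."""
    if set(vip.index) != set(p_values.index):
        raise ValueError("vip and p_values must cover the same features")
    p_values = p_values.reindex(vip.index)
    keep = (vip > vip_min) & (p_values < p_max)
    df = pd.DataFrame({"vip": vip[keep], "p": p_values[keep]})
    df.index.name = "feature_id"
    df = df.sort_values(["vip", "p"], ascending=[False, True])
    # deterministic tie-break on id
    df["_neg_vip"] = -df["vip"]
    df = df.reset_index().sort_values(["_neg_vip", "feature_id"]).drop(columns="_neg_vip")
    return df.reset_index(drop=True)
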