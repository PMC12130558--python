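"""Alpha diversity (Chao1, Shannon, Pielou) and Bray-Curtis PCoA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cohort import CohortTable, tss_normalize


@dataclass
class AlphaDiversity:
    sample_id: str
    observed: int
    chao1: float
    shannon: float  # nats
    pielou: float


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray      # (n, k), axes ordered by eigenvalue desc
    eigenvalues: np.ndarray      # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues, for kept axes


def alpha_diversity(counts, sample_id: str = "") -> AlphaDiversity:
    """Chao1 richness, Shannon entropy (nats) and Pielou evenness for one
    sample's genus counts.

    Chao1 = S_obs + F1(F1-1)/(2(F2+1)) with F1/F2 the singleton/doubleton
    counts; Pielou = H / ln(S_obs), defined as 1 for a single observed genus.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError(f"all-zero sample {sample_id!r}")
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = c[c > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    pielou = 1.0 if s_obs == 1 else shannon / np.log(s_obs)
    return AlphaDiversity(sample_id, s_obs, float(chao1), shannon, float(pielou))


def alpha_diversity_table(table: CohortTable) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(table.sample_ids):
        a = alpha_diversity(table.values[i], s)
        rows.append({
            "sample_id": s, "observed": a.observed, "chao1": a.chao1,
            "shannon": a.shannon, "pielou": a.pielou,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis_matrix(table: CohortTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity on TSS-normalized profiles.

    TSS to relative abundance is applied internally (idempotent), so raw
    count tables can be passed directly.
    """
    if (table.values.sum(axis=1) == 0).any():
        bad = [s for s, v in zip(table.sample_ids, table.values.sum(axis=1)) if v == 0]
        raise ValueError(f"all-zero samples: {bad[:5]}")
    rel = table if table.is_relative else tss_normalize(table, scale=1.0)
    d = squareform(pdist(rel.values, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def pcoa(distance: pd.DataFrame | np.ndarray, k: int = 2,
         sample_ids: list[str] | None = None) -> OrdinationResult:
    """Classical (metric) multidimensional scaling via Gower double-centering.

    Coordinates are built from positive eigenvalues only; negative
    eigenvalues (non-Euclidean part of the dissimilarity) are reported in
    ``eigenvalues`` but never embedded. Axis signs follow the
    largest-coordinate-positive convention so output is deterministic.
    """
    if isinstance(distance, pd.DataFrame):
        sample_ids = list(distance.index)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals).max())
    n_pos = int(pos.sum())
    if k > n_pos:
        import warnings

        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = evals[pos].sum()
    prop = evals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(
        sample_ids=sample_ids,
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=prop,
    )
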