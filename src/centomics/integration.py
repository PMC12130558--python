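"""Frailty stratification, metabolite-microbe Spearman networks, pathway
over-representation, and the key-metabolite selection rule.

The selection rule operationalizes the nomination of a single healthy-
longevity metabolite: it must carry the centenarian signature (elevated),
be elevated in healthy versus frail centenarians, and be positively
correlated with at least one gut genus in the filtered network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .cohort import CohortTable, SampleMetadata
from .stats import bh_adjust


@dataclass
class CorrelationEdge:
    metabolite_id: str
    genus_id: str
    genus_omic: str  # gut_genus | oral_genus
    rho: float
    p: float
    q: float


def frailty_stratify(
    metadata: list[SampleMetadata], fi_cut: int = 11
) -> dict[str, str]:
    """Split centenarians into healthy (FI < fi_cut) and frail (FI >= fi_cut)."""
    ce = [m for m in metadata if m.group == "CE"]
    if not ce:
        raise ValueError("no centenarian samples to stratify")
    strata = {}
    for m in ce:
        if m.frailty_index is None:
            raise ValueError(f"centenarian {m.sample_id!r} has no frailty index")
        strata[m.sample_id] = "HC" if m.frailty_index < fi_cut else "FC"
    return strata


def _rank_normalize(X: np.ndarray) -> np.ndarray:
    """Column-wise mid-rank transform, standardized for fast Spearman."""
    r = sps.rankdata(X, axis=0)
    r = r - r.mean(axis=0)
    sd = r.std(axis=0)
    sd[sd == 0] = np.nan  # constant columns: rho undefined, skipped later
    return r / sd


def correlation_network(
    metabolites: CohortTable,
    genera: CohortTable,
    sample_ids: list[str] | None = None,
    r_min: float = 0.2,
    p_max: float = 0.05,
) -> list[CorrelationEdge]:
    """All-pairs Spearman between a metabolite table and a genus table over
    shared samples; retain edges with |rho| >= r_min and raw p < p_max.

    BH q-values over the full pair family are reported on each retained
    edge, but the retention filter uses the raw p. Constant features are
    skipped.
    """
    shared = [s for s in metabolites.sample_ids if s in set(genera.sample_ids)]
    if sample_ids is not None:
        wanted = set(sample_ids)
        shared = [s for s in shared if s in wanted]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, have {len(shared)}")
    M = metabolites.subset_samples(shared)
    G = genera.subset_samples(shared)
    n = len(shared)
    zm = _rank_normalize(M.values)
    zg = _rank_normalize(G.values)
    rho = (zm.T @ zg) / n  # metabolites x genera; NaN where constant
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    valid = ~np.isnan(rho)
    q = np.full_like(p, np.nan)
    q[valid] = bh_adjust(p[valid].ravel())
    keep = valid & (np.abs(rho) >= r_min) & (p < p_max)
    edges = []
    for i, j in np.argwhere(keep):
        edges.append(
            CorrelationEdge(
                metabolite_id=M.feature_ids[i],
                genus_id=G.feature_ids[j],
                genus_omic=G.kind,
                rho=float(rho[i, j]),
                p=float(p[i, j]),
                q=float(q[i, j]),
            )
        )
    edges.sort(key=lambda e: (-abs(e.rho), e.metabolite_id, e.genus_id))
    return edges


def edges_frame(edges: list[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite_id": [e.metabolite_id for e in edges],
            "genus_id": [e.genus_id for e in edges],
            "genus_omic": [e.genus_omic for e in edges],
            "rho": [e.rho for e in edges],
            "p": [e.p for e in edges],
            "q": [e.q for e in edges],
        }
    )


def edges_to_graph(edges: list[CorrelationEdge]):
    """Bipartite metabolite-genus graph for GraphML export."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.metabolite_id, omic="metabolite")
        g.add_node(e.genus_id, omic=e.genus_omic)
        g.add_edge(e.metabolite_id, e.genus_id, rho=e.rho, p=e.p, q=e.q)
    return g


def pathway_ora(
    selected: set[str],
    universe: set[str],
    pathways,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per pathway.

    Pathway membership is intersected with the measured universe; pathways
    left empty are dropped with a warning. Rows sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected features must be a subset of the universe")
    N = len(universe)
    n = len(selected)
    rows = []
    for pid, members in pathways.members.items():
        inter = members & universe
        if not inter:
            import warnings

            warnings.warn(f"pathway {pid!r} disjoint from universe; dropped")
            continue
        K = len(inter)
        k = len(inter & selected)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": pathways.names.get(pid, pid),
                "overlap_k": k,
                "pathway_size_K": K,
                "selected_n": n,
                "universe_N": N,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "pathway_id"]).reset_index(drop=True)
    return df


def key_metabolite_select(
    ce_signatures: pd.DataFrame,
    hc_markers: pd.DataFrame,
    edges: list[CorrelationEdge],
) -> pd.DataFrame:
    """Rank candidate healthy-longevity metabolites.

    A candidate must be (a) centenarian-signature elevated, (b) present in
    the healthy-vs-frail marker list with HC-elevated direction, and (c)
    incident to at least one retained gut-genus edge with positive rho.
    Candidates are ranked by (gut edge count, max gut rho) descending.

    Parameters
    ----------
    ce_signatures : frame with feature_id, label, direction columns
    hc_markers : frame with feature_id and direction columns
        (direction "elevated" = higher in healthy centenarians); raise if
        missing, instructing to run the frailty stratification first.
    edges : retained correlation edges
    """
    for col in ("feature_id", "label", "direction"):
        if col not in ce_signatures.columns:
            raise ValueError(f"ce_signatures missing column {col!r}")
    if hc_markers is None or "feature_id" not in getattr(hc_markers, "columns", []):
        raise ValueError(
            "no healthy-vs-frail marker list: run frailty_stratify and the "
            "HC/FC marker screen first"
        )
    cent_up = set(
        ce_signatures.loc[
            (ce_signatures["label"] == "centenarian")
            & (ce_signatures["direction"] == "elevated"),
            "feature_id",
        ]
    )
    hc_up = set(
        hc_markers.loc[hc_markers.get("direction", "elevated") == "elevated", "feature_id"]
    )
    gut_edges: dict[str, list[CorrelationEdge]] = {}
    for e in edges:
        if e.genus_omic == "gut_genus" and e.rho > 0:
            gut_edges.setdefault(e.metabolite_id, []).append(e)
    rows = []
    for fid in sorted(cent_up & hc_up):
        incident = gut_edges.get(fid, [])
        if not incident:
            continue
        best = max(incident, key=lambda e: e.rho)
        rows.append(
            {
                "feature_id": fid,
                "n_gut_edges": len(incident),
                "max_rho": best.rho,
                "best_genus": best.genus_id,
            }
        )
    df = pd.DataFrame(rows, columns=["feature_id", "n_gut_edges", "max_rho", "best_genus"])
    if not df.empty:
        df = df.sort_values(
            ["n_gut_edges", "max_rho", "feature_id"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return df
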