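"""Three-signature classification of cohort features.

Every feature (serum metabolite or microbial genus) is assigned to exactly
one of four classes from the FDR pattern of its six pairwise group
comparisons (CE-CEL, CE-ELD, CE-YNG, CEL-ELD, CEL-YNG, ELD-YNG):

* centenarian signature — different in centenarians versus relatives and
  both control groups, with no elderly-vs-young difference;
* longevity-family signature — centenarians and their lineal relatives
  similar to each other but both distinct from the controls;
* aging signature — monotone change across young -> elderly -> centenarian
  with supporting significance;
* none.

Rules are evaluated in fixed precedence centenarian > family > aging, first
match wins, so the classes partition the feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GROUPS, CohortTable, SampleMetadata
from .stats import bh_adjust

COMPARISONS = (
    ("CE", "CEL"),
    ("CE", "ELD"),
    ("CE", "YNG"),
    ("CEL", "ELD"),
    ("CEL", "YNG"),
    ("ELD", "YNG"),
)


@dataclass
class PairwiseQMatrix:
    """Per-feature q-values/directions for the six group comparisons plus
    group medians. BH is applied within each comparison family across all
    features of one table."""

    feature_ids: list[str]
    q: pd.DataFrame          # features x 6 comparisons, BH-adjusted
    p: pd.DataFrame          # raw p
    direction: pd.DataFrame  # sign of median (tiebreak mean) difference
    medians: pd.DataFrame    # features x 4 groups


@dataclass
class SignatureResult:
    feature_id: str
    label: str      # centenarian | family | aging | none
    direction: str  # elevated | depleted | increasing | decreasing | none
    trace: str      # which clauses fired / failed


def _rank_sum_p_vectorized(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney normal approximation with tie and continuity
    correction, vectorized over feature columns."""
    import scipy.stats as sps

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=0)
    return np.minimum(1.0, np.asarray(res.pvalue, dtype=float))


def pairwise_group_tests(
    table: CohortTable,
    metadata: list[SampleMetadata],
    two_group_test: str = "wilcoxon",
) -> PairwiseQMatrix:
    """Rank tests per feature for the six group comparisons, BH within each
    comparison family."""
    by_group: dict[str, list[int]] = {g: [] for g in GROUPS}
    meta_by_id = {m.sample_id: m for m in metadata}
    for i, s in enumerate(table.sample_ids):
        if s not in meta_by_id:
            raise KeyError(f"sample {s!r} missing from metadata")
        by_group[meta_by_id[s].group].append(i)
    for g in GROUPS:
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples in the table")

    X = table.values
    cols = [f"{a}_{b}" for a, b in COMPARISONS]
    p = np.empty((table.n_features, len(COMPARISONS)))
    direction = np.empty_like(p)
    for ci, (a, b) in enumerate(COMPARISONS):
        xa, xb = X[by_group[a]], X[by_group[b]]
        if two_group_test == "ttest":
            import scipy.stats as sps

            p[:, ci] = sps.ttest_ind(xa, xb, equal_var=False, axis=0).pvalue
        else:
            p[:, ci] = _rank_sum_p_vectorized(xa, xb)
        d = np.median(xa, axis=0) - np.median(xb, axis=0)
        tie = d == 0
        if tie.any():
            d[tie] = xa[:, tie].mean(axis=0) - xb[:, tie].mean(axis=0)
        direction[:, ci] = np.sign(d)
    q = np.column_stack([bh_adjust(p[:, ci]) for ci in range(len(COMPARISONS))])
    medians = np.column_stack([np.median(X[by_group[g]], axis=0) for g in GROUPS])
    fid = list(table.feature_ids)
    return PairwiseQMatrix(
        feature_ids=fid,
        q=pd.DataFrame(q, index=fid, columns=cols),
        p=pd.DataFrame(p, index=fid, columns=cols),
        direction=pd.DataFrame(direction, index=fid, columns=cols),
        medians=pd.DataFrame(medians, index=fid, columns=list(GROUPS)),
    )


def _classify_one(
    q: dict[str, float],
    med: dict[str, float],
    alpha: float,
    family_requires_control_sig: bool,
) -> tuple[str, str, str]:
    trace = []

    # --- centenarian: CE differs from every other group, controls agree ---
    ce_all_sig = (
        q["CE_CEL"] < alpha and q["CE_ELD"] < alpha and q["CE_YNG"] < alpha
    )
    controls_same = q["ELD_YNG"] >= alpha
    ce_highest = med["CE"] > max(med["CEL"], med["ELD"], med["YNG"])
    ce_lowest = med["CE"] < min(med["CEL"], med["ELD"], med["YNG"])
    if ce_all_sig and controls_same and ce_highest:
        return "centenarian", "elevated", "CE>all q<a; ELD~YNG"
    if ce_all_sig and controls_same and ce_lowest:
        return "centenarian", "depleted", "CE<all q<a; ELD~YNG"
    trace.append(
        "cent:fail(%s)" % ("q" if not ce_all_sig else "ctrl" if not controls_same else "median")
    )

    # --- family: CE ~ CEL, both distinct from the controls ---
    fam_core = q["CE_CEL"] >= alpha and q["CE_ELD"] < alpha and q["CE_YNG"] < alpha
    fam_cel = (not family_requires_control_sig) or (
        q["CEL_ELD"] < alpha and q["CEL_YNG"] < alpha
    )
    fam_up = min(med["CE"], med["CEL"]) > max(med["ELD"], med["YNG"])
    fam_down = max(med["CE"], med["CEL"]) < min(med["ELD"], med["YNG"])
    if fam_core and fam_cel and fam_up:
        return "family", "elevated", "; ".join(trace + ["family:CE~CEL>ctrl"])
    if fam_core and fam_cel and fam_down:
        return "family", "depleted", "; ".join(trace + ["family:CE~CEL<ctrl"])
    trace.append("family:fail")

    # --- aging: strict median monotonicity over YNG -> ELD -> CE ---
    inc = med["YNG"] < med["ELD"] < med["CE"]
    dec = med["YNG"] > med["ELD"] > med["CE"]
    supported = q["CE_YNG"] < alpha and (q["CE_ELD"] < alpha or q["ELD_YNG"] < alpha)
    if inc and supported:
        return "aging", "increasing", "; ".join(trace + ["aging:inc"])
    if dec and supported:
        return "aging", "decreasing", "; ".join(trace + ["aging:dec"])
    trace.append("aging:fail")
    return "none", "none", "; ".join(trace)


def classify_feature_signatures(
    qmat: PairwiseQMatrix,
    alpha: float = 0.05,
    family_requires_control_sig: bool = True,
) -> list[SignatureResult]:
    out = []
    qdf, mdf = qmat.q, qmat.medians
    for fid in qmat.feature_ids:
        label, direction, trace = _classify_one(
            qdf.loc[fid].to_dict(), mdf.loc[fid].to_dict(), alpha,
            family_requires_control_sig,
        )
        out.append(SignatureResult(fid, label, direction, trace))
    return out


def signature_summary(results: list[SignatureResult], omic: str = "") -> pd.DataFrame:
    """Tabulate label x direction counts (TSV-ready)."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for label in ("centenarian", "family", "aging", "none"):
        for direction in ("elevated", "depleted", "increasing", "decreasing", "none"):
            n = sum(1 for r in results if r.label == label and r.direction == direction)
            if n or (label == "none" and direction == "none"):
                rows.append({"omic": omic, "label": label, "direction": direction, "count": n})
    return pd.DataFrame(rows)


def signatures_frame(results: list[SignatureResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "label": [r.label for r in results],
            "direction": [r.direction for r in results],
            "trace": [r.trace for r in results],
        }
    )
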