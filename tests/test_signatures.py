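"""Three-signature classification rules and their recovery on planted data."""

import numpy as np
import pandas as pd
import pytest

from centomics.cohort import tss_normalize
from centomics.signatures import (
    COMPARISONS,
    PairwiseQMatrix,
    classify_feature_signatures,
    pairwise_group_tests,
    signature_summary,
    signatures_frame,
)

COLS = [f"{a}_{b}" for a, b in COMPARISONS]


def make_qmatrix(rows):
    """rows: {feature_id: (qdict, mediandict)}"""
    fids = list(rows)
    q = pd.DataFrame([[rows[f][0][c] for c in COLS] for f in fids], index=fids, columns=COLS)
    med = pd.DataFrame(
        [[rows[f][1][g] for g in ("CE", "CEL", "ELD", "YNG")] for f in fids],
        index=fids, columns=["CE", "CEL", "ELD", "YNG"],
    )
    return PairwiseQMatrix(feature_ids=fids, q=q, p=q.copy(),
                           direction=q.copy() * 0, medians=med)


def q(**kw):
    base = {c: 1.0 for c in COLS}
    base.update(kw)
    return base


class TestClassificationRules:
    def test_all_nonsignificant_is_none(self):
        qm = make_qmatrix({"f": (q(), {"CE": 1, "CEL": 1, "ELD": 1, "YNG": 1})})
        res = classify_feature_signatures(qm)
        assert res[0].label == "none"
        assert res[0].direction == "none"

    def test_centenarian_elevated(self):
        qm = make_qmatrix({
            "f": (q(CE_CEL=0.01, CE_ELD=0.01, CE_YNG=0.01, ELD_YNG=0.5),
                  {"CE": 5, "CEL": 2, "ELD": 2, "YNG": 2})
        })
        r = classify_feature_signatures(qm)[0]
        assert (r.label, r.direction) == ("centenarian", "elevated")

    def test_centenarian_depleted_mirrors(self):
        qm = make_qmatrix({
            "f": (q(CE_CEL=0.01, CE_ELD=0.01, CE_YNG=0.01, ELD_YNG=0.5),
                  {"CE": 1, "CEL": 2, "ELD": 2, "YNG": 2})
        })
        r = classify_feature_signatures(qm)[0]
        assert (r.label, r.direction) == ("centenarian", "depleted")

    def test_family_elevated_requires_relative_control_significance(self):
        qd = q(CE_ELD=0.01, CE_YNG=0.01, CEL_ELD=0.01, CEL_YNG=0.01)
        med = {"CE": 5, "CEL": 5, "ELD": 2, "YNG": 2}
        r = classify_feature_signatures(make_qmatrix({"f": (qd, med)}))[0]
        assert (r.label, r.direction) == ("family", "elevated")
        # strict variant fails without CEL-vs-control significance...
        qd2 = q(CE_ELD=0.01, CE_YNG=0.01)
        r2 = classify_feature_signatures(make_qmatrix({"f": (qd2, med)}))[0]
        assert r2.label != "family"
        # ...but the permissive variant accepts it
        r3 = classify_feature_signatures(
            make_qmatrix({"f": (qd2, med)}), family_requires_control_sig=False
        )[0]
        assert (r3.label, r3.direction) == ("family", "elevated")

    def test_rule_trace_precedence_falls_through_to_aging(self):
        # centenarian fails on ELD-YNG significance, family on CE-CEL
        qd = q(CE_CEL=0.001, CE_ELD=0.004, CE_YNG=0.001, ELD_YNG=0.01,
               CEL_ELD=0.5, CEL_YNG=0.5)
        med = {"YNG": 1, "ELD": 2, "CE": 3, "CEL": 1.5}
        r = classify_feature_signatures(make_qmatrix({"f": (qd, med)}))[0]
        assert (r.label, r.direction) == ("aging", "increasing")
        assert "cent:fail" in r.trace and "family:fail" in r.trace

    def test_aging_decreasing_mirrors(self):
        qd = q(CE_YNG=0.01, CE_ELD=0.01, CE_CEL=0.5)
        med = {"YNG": 3, "ELD": 2, "CE": 1, "CEL": 3}
        r = classify_feature_signatures(make_qmatrix({"f": (qd, med)}))[0]
        assert (r.label, r.direction) == ("aging", "decreasing")

    def test_aging_needs_strict_monotone_medians(self):
        qd = q(CE_YNG=0.01, CE_ELD=0.01)
        med = {"YNG": 2, "ELD": 2, "CE": 3, "CEL": 2}  # tie breaks monotonicity
        r = classify_feature_signatures(make_qmatrix({"f": (qd, med)}))[0]
        assert r.label == "none"

    def test_labels_partition_features(self, small_bundle):
        qm = pairwise_group_tests(small_bundle.metabolites, small_bundle.metadata)
        res = classify_feature_signatures(qm)
        assert len(res) == small_bundle.metabolites.n_features
        assert {r.feature_id for r in res} == set(small_bundle.metabolites.feature_ids)
        summary = signature_summary(res, "metabolite")
        assert summary["count"].sum() == small_bundle.metabolites.n_features


class TestPairwiseGroupTests:
    def test_q_matrix_shape(self, small_bundle):
        qm = pairwise_group_tests(small_bundle.metabolites, small_bundle.metadata)
        assert qm.q.shape == (small_bundle.metabolites.n_features, 6)
        assert ((qm.q.values >= 0) & (qm.q.values <= 1)).all()

    def test_identical_feature_all_q_one(self, small_bundle):
        table = small_bundle.metabolites
        const = type(table)(
            feature_ids=["c0", "c1"],
            sample_ids=list(table.sample_ids),
            values=np.tile([[3.0, 7.0]], (table.n_samples, 1)),
            kind="metabolite",
        )
        qm = pairwise_group_tests(const, small_bundle.metadata)
        assert (qm.q.values == 1.0).all()
        assert (qm.direction.values == 0).all()

    def test_classification_invariant_to_monotone_transform(self, small_bundle):
        table = small_bundle.metabolites
        qm1 = pairwise_group_tests(table, small_bundle.metadata)
        transformed = type(table)(
            feature_ids=list(table.feature_ids),
            sample_ids=list(table.sample_ids),
            values=np.log1p(table.values) ** 2,
            kind="metabolite",
        )
        qm2 = pairwise_group_tests(transformed, small_bundle.metadata)
        r1 = signatures_frame(classify_feature_signatures(qm1))
        r2 = signatures_frame(classify_feature_signatures(qm2))
        pd.testing.assert_frame_equal(r1[["feature_id", "label", "direction"]],
                                      r2[["feature_id", "label", "direction"]])


class TestRecovery:
    def test_planted_metabolite_classes_recovered(self, bundle0):
        qm = pairwise_group_tests(bundle0.metabolites, bundle0.metadata)
        res = {r.feature_id: r for r in classify_feature_signatures(qm)}
        truth = bundle0.truth.frame
        planted = truth[(truth.omic == "metabolite")
                        & truth.label.isin(["centenarian", "family", "aging"])]
        for label, sub in planted.groupby("label"):
            hits = sum(
                res[r.feature_id].label == label and res[r.feature_id].direction == r.direction
                for r in sub.itertuples()
            )
            assert hits / len(sub) >= 0.90, f"{label}: {hits}/{len(sub)}"

    def test_swapping_control_groups_breaks_aging_monotonicity(self, bundle0):
        meta_swapped = []
        for m in bundle0.metadata:
            group = {"ELD": "YNG", "YNG": "ELD"}.get(m.group, m.group)
            meta_swapped.append(type(m)(m.sample_id, group, m.age, m.sex, m.bmi,
                                        m.frailty_index))
        qm = pairwise_group_tests(bundle0.metabolites, meta_swapped)
        res = {r.feature_id: r for r in classify_feature_signatures(qm)}
        truth = bundle0.truth.frame
        aging = truth[(truth.omic == "metabolite") & (truth.label == "aging")]
        still_increasing = sum(
            res[f].direction == "increasing" for f in aging.feature_id
        )
        # swapped controls invert the young < elderly step, so features can
        # no longer satisfy increasing monotonicity
        assert still_increasing == 0
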