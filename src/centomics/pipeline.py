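"""End-to-end analysis pipeline.

Stages run in dependency order over a cohort bundle (synthetic or loaded
from disk): signature classification per omic -> diversity -> centenarian-
vs-rest multivariate markers -> Venn intersections and logistic ROC panels
-> frailty stratification and HC/FC markers -> metabolite-microbe network
and pathway over-representation -> key-metabolite report. Every stage
writes TSVs into the run directory and the manifest is written last, so a
partial manifest marks an aborted run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    log_autoscale,
    prevalence_filter,
    read_cohort,
    read_gmt,
    tss_normalize,
)
from .config import AnalysisConfig
from .diversity import alpha_diversity_table, bray_curtis_matrix, pcoa
from .integration import (
    correlation_network,
    edges_frame,
    edges_to_graph,
    frailty_stratify,
    key_metabolite_select,
    pathway_ora,
)
from .markers import effect_screen_frame, evaluate_panel, lda_effect_screen
from .multivariate import plsda_fit, plsda_permutation_test, select_by_vip_p, vip_scores
from .signatures import (
    classify_feature_signatures,
    pairwise_group_tests,
    signature_summary,
    signatures_frame,
)
from .stats import anova_tukey_letters, wilcoxon_rank_sum
from .synthetic import CohortBundle, SynthSpec, generate_cohort, write_bundle

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_bundle(
    metabolites_path, gut_path, oral_path, metadata_path, pathways_path=None
) -> CohortBundle:
    met, metadata = read_cohort(metabolites_path, metadata_path, "metabolite")
    gut, _ = read_cohort(gut_path, metadata_path, "gut_genus")
    oral, _ = read_cohort(oral_path, metadata_path, "oral_genus")
    from .cohort import PathwayMap

    pathways = read_gmt(pathways_path) if pathways_path else PathwayMap(
        members={"pw_all": set(met.feature_ids)}, names={"pw_all": "all features"}
    )
    return CohortBundle(metabolites=met, gut=gut, oral=oral, metadata=metadata,
                        pathways=pathways)


def _two_group_p(table: CohortTable, mask: np.ndarray) -> pd.Series:
    """Per-feature Wilcoxon p for a binary split (class vs rest)."""
    import scipy.stats as sps

    res = sps.mannwhitneyu(
        table.values[mask], table.values[~mask],
        alternative="two-sided", method="asymptotic", axis=0,
    )
    return pd.Series(np.minimum(1.0, res.pvalue), index=table.feature_ids)


def run_pipeline(
    config: AnalysisConfig,
    bundle: CohortBundle | None = None,
    synth_spec: SynthSpec | None = None,
    outdir: str | Path = "centomics_run",
) -> dict:
    """Execute the full analysis; returns the run manifest (also written to
    ``manifest.json`` in the run directory)."""
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
        "inputs": {},
    }

    def done(stage: str, **outputs):
        manifest["stages"].append({"stage": stage, "status": "ok"})
        for k, v in outputs.items():
            manifest["outputs"][k] = str(v)
        log.info("stage %s done (%.1fs elapsed)", stage, time.time() - t_start)

    # ----- stage: inputs -----
    if bundle is None:
        if synth_spec is None:
            synth_spec = SynthSpec(seed=config.seed)
        bundle = generate_cohort(synth_spec)
        bpaths = write_bundle(bundle, outdir / "cohort")
        manifest["inputs"] = {k: _sha256(p) for k, p in bpaths.items()}
        done("synth", cohort_dir=outdir / "cohort")
    else:
        done("inputs")
    metadata = bundle.metadata
    groups = np.array([m.group for m in metadata])

    # ----- stage: signatures per omic -----
    signature_frames = {}
    for name, table, normalize in (
        ("metabolite", bundle.metabolites, False),
        ("gut", bundle.gut, True),
        ("oral", bundle.oral, True),
    ):
        t = tss_normalize(table, 1e6) if normalize else table
        qm = pairwise_group_tests(t, metadata, config.two_group_test)
        res = classify_feature_signatures(
            qm, config.alpha, config.family_requires_control_sig
        )
        sig = signatures_frame(res)
        signature_frames[name] = sig
        qm.q.to_csv(outdir / f"qmatrix_{name}.tsv", sep="\t")
        sig.to_csv(outdir / f"signatures_{name}.tsv", sep="\t", index=False)
        signature_summary(res, name).to_csv(
            outdir / f"signature_summary_{name}.tsv", sep="\t", index=False
        )
    done("signatures", signatures=outdir / "signatures_metabolite.tsv")

    # ----- stage: diversity -----
    for name, table in (("gut", bundle.gut), ("oral", bundle.oral)):
        alpha_df = alpha_diversity_table(table)
        alpha_df.to_csv(outdir / f"alpha_diversity_{name}.tsv", sep="\t")
        bc = bray_curtis_matrix(table)
        ord_res = pcoa(bc, k=2)
        coords = pd.DataFrame(
            ord_res.coordinates, index=ord_res.sample_ids,
            columns=[f"PCoA{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        coords.to_csv(outdir / f"pcoa_{name}.tsv", sep="\t")
        # group comparison letters on the first two axes
        letters = {}
        for ax in coords.columns:
            disp = anova_tukey_letters(
                {g: coords.loc[groups == g, ax].to_numpy() for g in np.unique(groups)},
                alpha=config.alpha,
            )
            letters[ax] = disp.letters
        pd.DataFrame(letters).to_csv(outdir / f"pcoa_letters_{name}.tsv", sep="\t")
    done("diversity", pcoa_gut=outdir / "pcoa_gut.tsv")

    # ----- stage: centenarian-vs-rest multivariate markers -----
    is_ce = groups == "CE"
    Z, kept = log_autoscale(bundle.metabolites)
    model = plsda_fit(Z, np.where(is_ce, "CE", "rest"), config.n_components, kept)
    vip = vip_scores(model)
    r2y, perm_p, _ = plsda_permutation_test(
        Z, np.where(is_ce, "CE", "rest"), config.n_components,
        config.n_permutations, seed=config.seed,
    )
    p_ce = _two_group_p(bundle.metabolites, is_ce).reindex(vip.index)
    met_markers = select_by_vip_p(vip, p_ce, config.vip_threshold_main, config.alpha)
    scores = pd.DataFrame(
        model.scores, index=bundle.metabolites.sample_ids,
        columns=[f"PC{i + 1}" for i in range(model.n_components)],
    )
    scores.to_csv(outdir / "plsda_scores_ce_vs_rest.tsv", sep="\t")
    vip.to_frame().join(p_ce.rename("p")).to_csv(outdir / "vip_ce_vs_rest.tsv", sep="\t")
    met_markers.to_csv(outdir / "markers_metabolite_ce_vs_rest.tsv", sep="\t", index=False)
    manifest["plsda_ce_vs_rest"] = {"r2y": r2y, "permutation_p": perm_p}
    done("multivariate", met_markers=outdir / "markers_metabolite_ce_vs_rest.tsv")

    # ----- stage: genus screens (CE vs rest) -----
    genus_screens = {}
    for name, table in (("gut", bundle.gut), ("oral", bundle.oral)):
        recs = lda_effect_screen(
            table, np.where(is_ce, "CE", "rest"),
            lda_min=config.lda_threshold_main,
            prevalence_min=config.prevalence_min,
            p_max=config.alpha,
        )
        df = effect_screen_frame(recs)
        genus_screens[name] = df
        df.to_csv(outdir / f"lda_screen_{name}_ce_vs_rest.tsv", sep="\t", index=False)
    done("genus_screens")

    # ----- stage: Venn intersections + panels -----
    def _sig_direction_map(sig: pd.DataFrame) -> dict[str, str]:
        cent = sig[sig["label"] == "centenarian"]
        return dict(zip(cent["feature_id"], cent["direction"]))

    panels = {}
    # metabolites: screen direction from median CE vs rest
    med_dir = {}
    for fid in met_markers["feature_id"]:
        j = bundle.metabolites.feature_ids.index(fid)
        col = bundle.metabolites.values[:, j]
        med_dir[fid] = (
            "elevated" if np.median(col[is_ce]) >= np.median(col[~is_ce]) else "depleted"
        )
    from .markers import intersect_sets

    shared_m, consistent_m, _ = intersect_sets(
        _sig_direction_map(signature_frames["metabolite"]), med_dir
    )
    venn_rows = [{"omic": "metabolite", "shared": len(shared_m),
                  "consistent": len(consistent_m)}]
    panel_specs = {}
    panel_specs["metabolite"] = (
        bundle.metabolites,
        sorted(f for f in consistent_m if med_dir[f] == "elevated")[:10],
    )
    for name in ("gut", "oral"):
        screen = genus_screens[name]
        passed = screen[screen["passes"]]
        screen_dir = {
            r.feature_id: ("elevated" if r.enriched_group == "CE" else "depleted")
            for r in passed.itertuples()
        }
        shared, consistent, _ = intersect_sets(
            _sig_direction_map(signature_frames[name]), screen_dir
        )
        venn_rows.append({"omic": name, "shared": len(shared), "consistent": len(consistent)})
        table = bundle.gut if name == "gut" else bundle.oral
        want = "elevated" if name == "gut" else "depleted"
        panel_specs[name] = (
            table, sorted(f for f in consistent if screen_dir[f] == want)[:13]
        )
    pd.DataFrame(venn_rows).to_csv(outdir / "venn_intersections.tsv", sep="\t", index=False)

    roc_rows = []
    for name, (table, feats) in panel_specs.items():
        if len(feats) < 1:
            log.warning("panel %s empty; skipped", name)
            continue
        sub = table.subset_features(feats)
        Zp, keptp = log_autoscale(sub)
        panel = evaluate_panel(Zp, is_ce.astype(int), keptp)
        panels[name] = panel
        pd.DataFrame({"fpr": panel.fpr, "tpr": panel.tpr}).to_csv(
            outdir / f"roc_{name}_ce_vs_rest.tsv", sep="\t", index=False
        )
        roc_rows.append({"panel": name, "n_features": len(keptp), "auc": panel.auc})
    pd.DataFrame(roc_rows).to_csv(outdir / "panel_auc.tsv", sep="\t", index=False)
    done("panels", panel_auc=outdir / "panel_auc.tsv")

    # ----- stage: frailty stratification + HC/FC markers -----
    strata = frailty_stratify(metadata, config.fi_cut)
    ce_samples = [s for s in bundle.metabolites.sample_ids if s in strata]
    hcfc = np.array([strata[s] for s in ce_samples])
    met_ce = bundle.metabolites.subset_samples(ce_samples)
    Zh, kept_h = log_autoscale(met_ce)
    model_h = plsda_fit(Zh, hcfc, config.n_components, kept_h)
    vip_h = vip_scores(model_h)
    p_h = _two_group_p(met_ce, hcfc == "HC").reindex(vip_h.index)
    hc_markers = select_by_vip_p(vip_h, p_h, config.vip_threshold_hcfc, config.alpha)
    hc_dir = []
    for fid in hc_markers["feature_id"]:
        j = met_ce.feature_ids.index(fid)
        col = met_ce.values[:, j]
        hc_dir.append(
            "elevated" if np.median(col[hcfc == "HC"]) >= np.median(col[hcfc == "FC"])
            else "depleted"
        )
    hc_markers = hc_markers.assign(direction=hc_dir)
    hc_markers.to_csv(outdir / "markers_metabolite_hc_vs_fc.tsv", sep="\t", index=False)
    pd.Series(strata, name="stratum").rename_axis("sample_id").to_csv(
        outdir / "frailty_strata.tsv", sep="\t"
    )
    for name, table in (("gut", bundle.gut), ("oral", bundle.oral)):
        tab_ce = table.subset_samples(ce_samples)
        recs = lda_effect_screen(
            tab_ce, hcfc, lda_min=config.lda_threshold_hcfc,
            prevalence_min=config.prevalence_min, p_max=config.alpha,
        )
        effect_screen_frame(recs).to_csv(
            outdir / f"lda_screen_{name}_hc_vs_fc.tsv", sep="\t", index=False
        )
    done("frailty", hc_markers=outdir / "markers_metabolite_hc_vs_fc.tsv")

    # ----- stage: correlation network -----
    sig_met = signature_frames["metabolite"]
    cent_up = set(
        sig_met.loc[(sig_met["label"] == "centenarian")
                    & (sig_met["direction"] == "elevated"), "feature_id"]
    )
    candidates = sorted(cent_up | set(hc_markers["feature_id"]))
    edges = []
    edges_ce = []
    if candidates:
        met_sub = bundle.metabolites.subset_features(candidates)
        for genus_table in (bundle.gut, bundle.oral):
            # cohort-wide network: the reported metabolite-microbe map
            edges += correlation_network(
                met_sub, genus_table, r_min=config.corr_r_min, p_max=config.corr_p_max
            )
            # within-centenarian network: group structure removed, used for
            # the healthy-longevity key-metabolite ranking
            edges_ce += correlation_network(
                met_sub, genus_table, sample_ids=ce_samples,
                r_min=config.corr_r_min, p_max=config.corr_p_max,
            )
    edf = edges_frame(edges)
    edf.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    edges_frame(edges_ce).to_csv(outdir / "network_edges_within_ce.tsv", sep="\t", index=False)
    try:
        import networkx as nx

        nx.write_graphml(edges_to_graph(edges), outdir / "network.graphml")
    except Exception as exc:  # pragma: no cover - export is best-effort
        log.warning("GraphML export failed: %s", exc)
    done("network", network=outdir / "network_edges.tsv")

    # ----- stage: pathway over-representation -----
    universe = set(bundle.metabolites.feature_ids)
    selected = set(met_markers["feature_id"])
    ora = pathway_ora(selected, universe, bundle.pathways)
    ora.to_csv(outdir / "pathway_ora.tsv", sep="\t", index=False)
    done("ora", ora=outdir / "pathway_ora.tsv")

    # ----- stage: key-metabolite report -----
    report = key_metabolite_select(sig_met, hc_markers, edges_ce)
    report.to_csv(outdir / "key_metabolite_report.tsv", sep="\t", index=False)
    done("key_metabolite", report=outdir / "key_metabolite_report.tsv")

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
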