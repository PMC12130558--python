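"""Synthetic four-group cohort generator with planted ground truth.

Emulates a centenarian study design: serum metabolite intensities
(log-normal), gut and oral genus counts (Dirichlet-multinomial at Poisson
sequencing depth), a frailty-index split of the centenarians, and one "key"
tryptophan-like metabolite coupled to one gut genus at a target Spearman
correlation.

Planted effect patterns mirror the three signature definitions:

* centenarian features shift only in the CE group;
* longevity-family features shift in CE and CEL;
* aging features shift linearly over YNG (0) -> ELD (1/2) -> CE (1), with
  CEL untouched so the three patterns stay mutually distinguishable.

Healthy-vs-frail (HC/FC) marker metabolites are planted on otherwise-null
features, except the key metabolite, which is both centenarian-elevated and
HC-elevated — by construction the only feature satisfying every clause of
the key-metabolite selection rule.

All randomness flows from one master seed through independent per-table
streams, so regenerating one table never perturbs the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sps

from .cohort import (
    CohortTable,
    PathwayMap,
    SampleMetadata,
    write_cohort,
    write_gmt,
    write_metadata,
)

log = logging.getLogger(__name__)

GROUP_SIZES_DEFAULT = (145, 126, 92, 62)  # CE, CEL, ELD, YNG
AGE_RANGES = {"CE": (100, 116), "CEL": (24, 86), "ELD": (65, 88), "YNG": (23, 54)}


@dataclass
class SynthSpec:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the cohort geometry of the emulated study: 425
    participants (145/126/92/62), 808 serum metabolites with 21 centenarian-
    elevated / 26 centenarian-depleted / 36 family-elevated / 21 aging-
    increasing planted features, 250 gut genera (16/9/6 planted), 200 oral
    genera (4 depleted / 7 elevated / 0), an 81/64 healthy/frail centenarian
    split at frailty index 11, and one key metabolite coupled to one gut
    genus at Spearman rho 0.4.
    """

    n_per_group: tuple[int, int, int, int] = GROUP_SIZES_DEFAULT
    n_metabolites: int = 808
    n_gut_genera: int = 250
    n_oral_genera: int = 200
    met_cent_elevated: int = 21
    met_cent_depleted: int = 26
    met_family_elevated: int = 36
    met_aging_increasing: int = 21
    gut_cent: int = 16
    gut_family: int = 9
    gut_aging: int = 6
    oral_cent: int = 4
    oral_family: int = 7
    oral_aging: int = 0
    effect_size_log: float = 1.0
    hc_n: int = 81
    fc_n: int = 64
    hc_marker_n: int = 11  # pure HC-vs-FC markers, in addition to the key metabolite
    key_metabolite_index: int = 0  # within the centenarian-elevated block
    key_gut_genus_index: int | None = None  # default: first planted cent gut genus
    key_rho: float = 0.4
    # optional centenarian elevation of the key genus (fraction of
    # effect_size_log); zero keeps the pooled key-pair correlation centered
    # on the coupling target instead of inflating it with group separation
    key_genus_effect_scale: float = 0.0
    depth_mean: float = 30000.0
    met_sigma: float = 0.5
    gut_concentration: float = 150.0
    gut_decay: float = 0.7
    oral_concentration: float = 120.0
    oral_decay: float = 0.7
    fi_cut: int = 11
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("group sizes must be positive")
        n_met_planted = (
            self.met_cent_elevated + self.met_cent_depleted
            + self.met_family_elevated + self.met_aging_increasing
            + self.hc_marker_n
        )
        if n_met_planted > self.n_metabolites:
            raise ValueError("planted metabolites exceed n_metabolites")
        if self.gut_cent + self.gut_family + self.gut_aging > self.n_gut_genera:
            raise ValueError("planted gut genera exceed n_gut_genera")
        if self.oral_cent + self.oral_family + self.oral_aging > self.n_oral_genera:
            raise ValueError("planted oral genera exceed n_oral_genera")
        if self.hc_n + self.fc_n != self.n_per_group[0]:
            raise ValueError("hc_n + fc_n must equal the CE group size")
        if not 0 <= self.key_metabolite_index < max(1, self.met_cent_elevated):
            raise ValueError("key metabolite index outside the centenarian-elevated block")
        if not -1 < self.key_rho < 1:
            raise ValueError("key_rho must be in (-1, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class PlantedTruth:
    """Ground truth written by the generator, oracle for recovery tests."""

    frame: pd.DataFrame  # omic, feature_id, label, direction, effect, partner
    key_metabolite: str
    key_genus: str
    key_rho: float
    hc_samples: list[str]
    fc_samples: list[str]

    def planted(self, omic: str, label: str, direction: str | None = None) -> set[str]:
        f = self.frame
        m = (f["omic"] == omic) & (f["label"] == label)
        if direction is not None:
            m &= f["direction"] == direction
        return set(f.loc[m, "feature_id"])


@dataclass
class CohortBundle:
    metabolites: CohortTable
    gut: CohortTable
    oral: CohortTable
    metadata: list[SampleMetadata] = field(default_factory=list)
    pathways: PathwayMap = field(default_factory=PathwayMap)
    truth: PlantedTruth | None = None


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _group_vector(spec: SynthSpec) -> np.ndarray:
    groups = []
    for g, n in zip(("CE", "CEL", "ELD", "YNG"), spec.n_per_group):
        groups += [g] * n
    return np.array(groups)


def _metabolite_shift_patterns(spec: SynthSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-feature, per-group mean shifts (natural-log units) and the planted
    block index ranges."""
    e = spec.effect_size_log
    n = spec.n_metabolites
    shifts = {g: np.zeros(n) for g in ("CE", "CEL", "ELD", "YNG")}
    i0 = 0
    blocks = {}
    for name, count in (
        ("cent_elevated", spec.met_cent_elevated),
        ("cent_depleted", spec.met_cent_depleted),
        ("family_elevated", spec.met_family_elevated),
        ("aging_increasing", spec.met_aging_increasing),
        ("hc_marker", spec.hc_marker_n),
    ):
        blocks[name] = np.arange(i0, i0 + count)
        i0 += count
    shifts["CE"][blocks["cent_elevated"]] += e
    shifts["CE"][blocks["cent_depleted"]] -= e
    shifts["CE"][blocks["family_elevated"]] += e
    shifts["CEL"][blocks["family_elevated"]] += e
    shifts["CE"][blocks["aging_increasing"]] += e
    shifts["ELD"][blocks["aging_increasing"]] += e / 2.0
    return blocks, shifts


def _genus_plan(
    n_cent: int, n_family: int, n_aging: int, cent_mode: str = "mixed"
) -> list[tuple[int, str, float]]:
    """Lay planted genera out over the abundance ranks as (index, label, sign).

    Aging genera sit on the most abundant ranks (indices 2..), alternating
    increasing/decreasing, because the half-size elderly shift is only
    detectable where compositional noise is small. Family genera come next
    (abundant ranks, where the centenarian-vs-relative equality they must
    exhibit is robust to compositional spillover); centenarian genera sit on
    mid ranks, depleted half first, elevated half second. Mixing directions
    keeps the total planted mass roughly balanced across groups.
    """
    plan: list[tuple[int, str, float]] = []
    n_dep = {"mixed": n_cent // 2, "elevated": 0, "depleted": n_cent}[cent_mode]
    # aging: decreasing genera on the heavier ranks, more of them than
    # increasing ones, because a fold elevation (e - 1) adds more mass than
    # a fold depletion (1 - 1/e) removes
    n_aging_dec = (2 * n_aging) // 3
    for i in range(n_aging):
        plan.append((2 + i, "aging", -1.0 if i < n_aging_dec else +1.0))
    dep_start = 2 + max(n_aging, 6)
    for i in range(n_dep):
        plan.append((dep_start + i, "cent", -1.0))
    fam_start = dep_start + n_dep + 1
    for i in range(n_family):
        plan.append((fam_start + i, "family", +1.0))
    # elevated centenarian genera on rarer ranks: the multiplicative boost
    # on light ranks roughly offsets the depleted mass on heavy ranks,
    # keeping the CE-vs-CEL compositional gap near zero so family genera
    # are not spuriously split between centenarians and their relatives
    elev_start = fam_start + max(n_family, 9) + 18
    for i in range(n_cent - n_dep):
        plan.append((elev_start + i, "cent", +1.0))
    return plan


def _genus_alpha(
    n_genera: int,
    concentration: float,
    decay: float,
    plan: list[tuple[int, str, float]],
    effect: float,
) -> dict[str, np.ndarray]:
    """Group-specific Dirichlet concentration vectors with planted log-fold
    effects on the signature patterns."""
    w = (np.arange(1, n_genera + 1, dtype=float)) ** (-decay)
    base = concentration * w / w.sum()
    alphas = {g: base.copy() for g in ("CE", "CEL", "ELD", "YNG")}
    for idx, label, sign in plan:
        if idx >= n_genera:
            raise ValueError("planted genus index exceeds table size")
        if label == "cent":
            alphas["CE"][idx] *= np.exp(sign * effect)
        elif label == "family":
            alphas["CE"][idx] *= np.exp(sign * effect)
            alphas["CEL"][idx] *= np.exp(sign * effect)
        elif label == "aging":
            alphas["CE"][idx] *= np.exp(sign * effect)
            alphas["ELD"][idx] *= np.exp(sign * effect / 2.0)
    return alphas


def _sample_counts(
    rng: np.random.Generator,
    groups: np.ndarray,
    alphas: dict[str, np.ndarray],
    depth_mean: float,
) -> np.ndarray:
    n = groups.size
    counts = np.zeros((n, alphas["CE"].size), dtype=int)
    for i in range(n):
        p = rng.dirichlet(alphas[groups[i]])
        depth = max(1, int(rng.poisson(depth_mean)))
        counts[i] = rng.multinomial(depth, p)
    return counts


def _rank_normal(x: np.ndarray) -> np.ndarray:
    """Mid-rank inverse-normal scores (Gaussian copula marginal)."""
    r = sps.rankdata(x)
    return sps.norm.ppf(r / (x.size + 1.0))


def _rank_normal_within(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Inverse-normal scores computed within each group, so the result
    carries no between-group signal."""
    z = np.empty_like(x, dtype=float)
    for g in np.unique(groups):
        m = groups == g
        z[m] = _rank_normal(x[m])
    return z


def _calibrate_key_column(
    rel_genus: np.ndarray,
    shifts: np.ndarray,
    mu: float,
    sigma: float,
    eps: np.ndarray,
    target_rho: float,
    eval_mask: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Build the key metabolite's log-intensities so the Spearman rho with
    the genus's relative abundance hits the target.

    The coupling weight lambda of a Gaussian copula is found by bisection,
    with rho evaluated over ``eval_mask`` (default: all samples). The copula
    scores are ranked within groups when ``groups`` is given, so the
    coupling is a genuine within-group association rather than an artifact
    of both features being elevated in centenarians; any additional pooled
    correlation then comes only from the planted group shifts themselves.
    """
    if groups is not None:
        z = _rank_normal_within(rel_genus, groups)
    else:
        z = _rank_normal(rel_genus)
    if eval_mask is None:
        eval_mask = np.ones(rel_genus.size, dtype=bool)

    def col(lam: float) -> np.ndarray:
        noise = lam * z + np.sqrt(max(0.0, 1.0 - lam * lam)) * eps
        return mu + shifts + sigma * noise

    def rho_of(lam: float) -> float:
        vals = np.exp(col(lam))
        return float(sps.spearmanr(vals[eval_mask], rel_genus[eval_mask]).statistic)

    lo, hi = -0.99, 0.99
    if rho_of(lo) >= target_rho:
        lam = lo
    elif rho_of(hi) <= target_rho:
        lam = hi
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if rho_of(mid) < target_rho:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
    log.info("key-pair coupling calibrated: lambda=%.4f, rho=%.4f", lam, rho_of(lam))
    return col(lam)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate_cohort(spec: SynthSpec) -> CohortBundle:
    """Generate the full synthetic bundle deterministically from spec.seed."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_meta, rng_met, rng_gut, rng_oral, rng_pw, rng_key = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    groups = _group_vector(spec)
    n = groups.size
    sample_ids = []
    counters = {g: 0 for g in ("CE", "CEL", "ELD", "YNG")}
    for g in groups:
        counters[g] += 1
        sample_ids.append(f"{g}{counters[g]:04d}")

    # --- metadata with exact HC/FC split ---
    ce_idx = np.flatnonzero(groups == "CE")
    perm = rng_meta.permutation(ce_idx.size)
    hc_local = set(perm[: spec.hc_n].tolist())
    fi = {}
    for local, gi in enumerate(ce_idx):
        if local in hc_local:
            fi[gi] = int(rng_meta.integers(0, spec.fi_cut))
        else:
            fi[gi] = int(rng_meta.integers(spec.fi_cut, spec.fi_cut + 15))
    metadata = []
    for i, (sid, g) in enumerate(zip(sample_ids, groups)):
        lo, hi = AGE_RANGES[g]
        metadata.append(
            SampleMetadata(
                sample_id=sid,
                group=g,
                age=float(np.round(rng_meta.uniform(lo, hi), 1)),
                sex=str(rng_meta.choice(["F", "M"])),
                bmi=float(np.round(rng_meta.normal(21.5 if g == "CE" else 23.0, 2.5), 1)),
                frailty_index=fi.get(i),
            )
        )
    hc_samples = [sample_ids[gi] for gi in ce_idx if fi[gi] < spec.fi_cut]
    fc_samples = [sample_ids[gi] for gi in ce_idx if fi[gi] >= spec.fi_cut]
    is_hc = np.array([fi.get(i, -1) >= 0 and fi.get(i) < spec.fi_cut for i in range(n)])
    is_fc = np.array([fi.get(i, -1) >= spec.fi_cut for i in range(n)])

    # --- gut genus counts ---
    gut_plan = _genus_plan(spec.gut_cent, spec.gut_family, spec.gut_aging, "mixed")
    # the key genus is a mid-abundance genus outside the signature blocks
    # with a mild centenarian elevation
    planted_gut_idx = {i for i, _, _ in gut_plan}
    if spec.key_gut_genus_index is not None:
        key_gut_j = int(spec.key_gut_genus_index)
    else:
        key_gut_j = 2 + max(spec.gut_aging, 6) + spec.gut_cent // 2 + 1 \
            + max(spec.gut_family, 9) + 2
    gut_alphas = _genus_alpha(
        spec.n_gut_genera, spec.gut_concentration, spec.gut_decay,
        gut_plan, spec.effect_size_log,
    )
    if key_gut_j not in planted_gut_idx:
        gut_alphas["CE"][key_gut_j] *= np.exp(
            spec.key_genus_effect_scale * spec.effect_size_log
        )
    gut_counts = _sample_counts(rng_gut, groups, gut_alphas, spec.depth_mean)
    gut_ids = [f"gut_g{i + 1:04d}" for i in range(spec.n_gut_genera)]

    # --- oral genus counts (centenarian genera depleted, family elevated) ---
    oral_plan = _genus_plan(spec.oral_cent, spec.oral_family, spec.oral_aging, "depleted")
    oral_alphas = _genus_alpha(
        spec.n_oral_genera, spec.oral_concentration, spec.oral_decay,
        oral_plan, spec.effect_size_log,
    )
    oral_counts = _sample_counts(rng_oral, groups, oral_alphas, spec.depth_mean)
    oral_ids = [f"oral_g{i + 1:04d}" for i in range(spec.n_oral_genera)]

    # --- metabolite intensities ---
    blocks, shifts = _metabolite_shift_patterns(spec)
    e = spec.effect_size_log
    mu = rng_met.normal(10.0, 1.0, spec.n_metabolites)
    logx = mu[None, :] + rng_met.normal(0.0, spec.met_sigma, (n, spec.n_metabolites))
    for g in ("CE", "CEL", "ELD", "YNG"):
        logx[groups == g] += shifts[g][None, :]
    # HC/FC contrast: +-e/2 around the CE mean so the CE-level pattern is kept
    hcfc_features = np.concatenate([
        blocks["hc_marker"],
        [blocks["cent_elevated"][spec.key_metabolite_index]],
    ]).astype(int)
    logx[np.ix_(is_hc, hcfc_features)] += e / 2.0
    logx[np.ix_(is_fc, hcfc_features)] -= e / 2.0

    # --- key metabolite column coupled to the key gut genus ---
    key_met_j = int(blocks["cent_elevated"][spec.key_metabolite_index])
    rel_key_genus = gut_counts[:, key_gut_j] / np.maximum(gut_counts.sum(axis=1), 1)
    key_shifts = np.zeros(n)
    for g in ("CE", "CEL", "ELD", "YNG"):
        key_shifts[groups == g] = shifts[g][key_met_j]
    key_shifts[is_hc] += e / 2.0
    key_shifts[is_fc] -= e / 2.0
    eps = rng_key.normal(0.0, 1.0, n)
    logx[:, key_met_j] = _calibrate_key_column(
        rel_key_genus, key_shifts, mu[key_met_j], spec.met_sigma, eps, spec.key_rho,
        eval_mask=(groups == "CE"), groups=groups,
    )
    met_values = np.exp(logx)
    met_ids = [f"met_{i + 1:04d}" for i in range(spec.n_metabolites)]

    # --- pathway annotation: one tryptophan-like pathway holding the key ---
    trp_members = {met_ids[key_met_j]}
    trp_members |= {met_ids[j] for j in blocks["cent_elevated"][:10]}
    null_start = int(blocks["hc_marker"][-1]) + 1 if spec.hc_marker_n else key_met_j + 1
    null_pool = np.arange(null_start, spec.n_metabolites)
    trp_members |= {met_ids[j] for j in rng_pw.choice(null_pool, size=min(9, null_pool.size), replace=False)}
    members = {"pw_trp": trp_members}
    names = {"pw_trp": "tryptophan metabolism (synthetic)"}
    for pi in range(11):
        size = int(rng_pw.integers(15, 31))
        mem = rng_pw.choice(spec.n_metabolites, size=size, replace=False)
        members[f"pw_{pi + 2:02d}"] = {met_ids[j] for j in mem}
        names[f"pw_{pi + 2:02d}"] = f"synthetic pathway {pi + 2}"
    pathways = PathwayMap(members=members, names=names)

    # --- planted truth ---
    rows = []
    for name, label, direction in (
        ("cent_elevated", "centenarian", "elevated"),
        ("cent_depleted", "centenarian", "depleted"),
        ("family_elevated", "family", "elevated"),
        ("aging_increasing", "aging", "increasing"),
        ("hc_marker", "hc_marker", "elevated"),
    ):
        for j in blocks[name]:
            rows.append({
                "omic": "metabolite", "feature_id": met_ids[j], "label": label,
                "direction": direction, "effect": e, "partner": "",
            })
    def _dir(label: str, sign: float) -> str:
        if label == "aging":
            return "increasing" if sign > 0 else "decreasing"
        return "elevated" if sign > 0 else "depleted"

    for omic, ids, plan in (("gut_genus", gut_ids, gut_plan), ("oral_genus", oral_ids, oral_plan)):
        for j, label, sign in plan:
            rows.append({
                "omic": omic, "feature_id": ids[j],
                "label": {"cent": "centenarian"}.get(label, label),
                "direction": _dir(label, sign), "effect": sign * e, "partner": "",
            })
    rows.append({
        "omic": "pair", "feature_id": met_ids[key_met_j], "label": "key_pair",
        "direction": "positive", "effect": spec.key_rho, "partner": gut_ids[key_gut_j],
    })
    truth = PlantedTruth(
        frame=pd.DataFrame(rows),
        key_metabolite=met_ids[key_met_j],
        key_genus=gut_ids[key_gut_j],
        key_rho=spec.key_rho,
        hc_samples=hc_samples,
        fc_samples=fc_samples,
    )

    return CohortBundle(
        metabolites=CohortTable(met_ids, sample_ids, met_values, "metabolite"),
        gut=CohortTable(gut_ids, sample_ids, gut_counts.astype(float), "gut_genus"),
        oral=CohortTable(oral_ids, sample_ids, oral_counts.astype(float), "oral_genus"),
        metadata=metadata,
        pathways=pathways,
        truth=truth,
    )


def truth_table(bundle: CohortBundle) -> pd.DataFrame:
    """TSV-ready planted-truth records (one row per planted feature plus the
    key-pair line)."""
    if bundle.truth is None:
        raise ValueError("bundle carries no planted truth")
    return bundle.truth.frame.copy()


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit the TSV/GMT dialects consumed by the readers, plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolites": outdir / "metabolites.tsv",
        "gut": outdir / "gut_genera.tsv",
        "oral": outdir / "oral_genera.tsv",
        "metadata": outdir / "metadata.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_cohort(bundle.metabolites, paths["metabolites"])
    write_cohort(bundle.gut, paths["gut"])
    write_cohort(bundle.oral, paths["oral"])
    write_metadata(bundle.metadata, paths["metadata"])
    write_gmt(bundle.pathways, paths["pathways"])
    if bundle.truth is not None:
        truth_table(bundle).to_csv(paths["truth"], sep="\t", index=False)
    return paths
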