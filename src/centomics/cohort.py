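"""Cohort data model: abundance tables, sample metadata, pathway maps.

On disk, feature tables follow the common omics dialect (features in rows,
samples in columns, tab-separated); in memory everything is oriented samples
in rows, features in columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUPS = ("CE", "CEL", "ELD", "YNG")


@dataclass
class SampleMetadata:
    """One cohort participant.

    ``frailty_index`` is required for centenarians (group CE) and must be
    absent for everyone else.
    """

    sample_id: str
    group: str
    age: float | None = None
    sex: str = "unknown"
    bmi: float | None = None
    frailty_index: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sample {self.sample_id!r}: bad sex {self.sex!r}")
        if self.group == "CE":
            if self.frailty_index is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: centenarian without frailty_index"
                )
            if self.frailty_index < 0:
                raise ValueError(f"sample {self.sample_id!r}: negative frailty_index")
        elif self.frailty_index is not None:
            raise ValueError(
                f"sample {self.sample_id!r}: frailty_index given for non-CE sample"
            )


@dataclass
class CohortTable:
    """Samples x features abundance matrix with a feature kind tag."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_features), non-negative
    kind: str  # metabolite | gut_genus | oral_genus
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_s, n_f = self.values.shape
        if n_s != len(self.sample_ids) or n_f != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != n_f:
            raise ValueError("duplicate feature ids")
        if self.kind not in ("metabolite", "gut_genus", "oral_genus"):
            raise ValueError(f"bad table kind {self.kind!r}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"non-numeric cell at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        """Samples-in-rows DataFrame view."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids: list[str]) -> "CohortTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return CohortTable(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[rows],
            kind=self.kind,
            is_relative=self.is_relative,
        )

    def subset_features(self, feature_ids: list[str]) -> "CohortTable":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"features not in table: {missing[:5]}")
        cols = [idx[f] for f in feature_ids]
        return CohortTable(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[:, cols],
            kind=self.kind,
            is_relative=False if len(cols) < self.n_features else self.is_relative,
        )


@dataclass
class PathwayMap:
    """pathway_id -> member feature ids, with display names."""

    members: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, mem in self.members.items():
            if not mem:
                raise ValueError(f"pathway {pid!r} has no members")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: metadata needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _opt(key, cast):
            v = d.get(key)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return cast(v)

        sex = d.get("sex")
        if sex is None or (isinstance(sex, float) and math.isnan(sex)) or sex == "":
            sex = "unknown"
        records.append(
            SampleMetadata(
                sample_id=str(d["sample_id"]),
                group=str(d["group"]),
                age=_opt("age", float),
                sex=str(sex),
                bmi=_opt("bmi", float),
                frailty_index=_opt("frailty_index", lambda v: int(float(v))),
            )
        )
    return records


def write_metadata(metadata: list[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "group": [m.group for m in metadata],
            "age": [m.age for m in metadata],
            "sex": [m.sex for m in metadata],
            "bmi": [m.bmi for m in metadata],
            "frailty_index": [m.frailty_index for m in metadata],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_cohort(
    table_path: str | Path,
    metadata_path: str | Path,
    kind: str,
) -> tuple[CohortTable, list[SampleMetadata]]:
    """Read a features x samples TSV plus metadata; intersect sample sets.

    Sample order follows the metadata file. Samples present in only one of
    the two files are dropped with a log report.
    """
    metadata = read_metadata(metadata_path)
    df = pd.read_csv(table_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{table_path}: duplicate feature id {df.index[df.index.duplicated()][0]!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"{table_path}: duplicate sample column")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"{table_path}: non-numeric cell at feature {bad!r}, sample {col!r}"
            )
    table_samples = set(df.columns.astype(str))
    kept = [m for m in metadata if m.sample_id in table_samples]
    dropped_meta = [m.sample_id for m in metadata if m.sample_id not in table_samples]
    dropped_table = sorted(table_samples - {m.sample_id for m in metadata})
    if dropped_meta:
        log.info("dropped %d metadata samples absent from table: %s",
                 len(dropped_meta), dropped_meta[:10])
    if dropped_table:
        log.info("dropped %d table samples absent from metadata: %s",
                 len(dropped_table), dropped_table[:10])
    order = [m.sample_id for m in kept]
    table = CohortTable(
        feature_ids=[str(f) for f in df.index],
        sample_ids=order,
        values=df[order].to_numpy(dtype=float).T,
        kind=kind,
    )
    return table, kept


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the canonical features x samples TSV dialect."""
    df = pd.DataFrame(
        table.values.T, index=table.feature_ids, columns=table.sample_ids
    )
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> PathwayMap:
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs id, description, >=1 member: {line[:60]!r}")
        pid, desc, *mem = parts
        members[pid] = set(mem)
        names[pid] = desc
    return PathwayMap(members=members, names=names)


def write_gmt(pathways: PathwayMap, path: str | Path) -> None:
    lines = []
    for pid in sorted(pathways.members):
        mem = sorted(pathways.members[pid])
        lines.append("\t".join([pid, pathways.names.get(pid, pid)] + mem))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# normalization primitives
# ---------------------------------------------------------------------------

def tss_normalize(table: CohortTable, scale: float = 1e6) -> CohortTable:
    """Total-sum scaling: each sample row rescaled to sum to ``scale``."""
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"all-zero samples cannot be normalized: {[table.sample_ids[i] for i in zero[:5]]}"
        )
    return CohortTable(
        feature_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
        values=table.values / sums[:, None] * scale,
        kind=table.kind,
        is_relative=True,
    )


def prevalence_filter(
    table: CohortTable,
    min_fraction: float,
    as_mean_abundance: bool = False,
) -> tuple[CohortTable, list[str]]:
    """Keep features detected in strictly more than ``min_fraction`` of samples.

    With ``as_mean_abundance=True`` the alternative reading is used instead:
    keep features whose mean relative abundance exceeds ``min_fraction``.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    if as_mean_abundance:
        rel = table.values / np.maximum(table.values.sum(axis=1, keepdims=True), 1e-300)
        stat = rel.mean(axis=0)
    else:
        stat = (table.values > 0).mean(axis=0)
    keep = stat > min_fraction
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    if removed:
        log.info("prevalence filter removed %d/%d features", len(removed), table.n_features)
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    out = CohortTable(
        feature_ids=kept_ids,
        sample_ids=list(table.sample_ids),
        values=table.values[:, keep],
        kind=table.kind,
        is_relative=False,
    )
    return out, removed


def log_autoscale(
    table: CohortTable, pseudocount: float | None = None
) -> tuple[np.ndarray, list[str]]:
    """log(x + pseudocount) then per-feature autoscaling to mean 0, sd 1.

    Constant features (zero variance after the log) are dropped with a log
    entry. Default pseudocount is half the smallest nonzero value in the
    table (0 if the table has no zeros). Returns (matrix, kept feature ids).
    """
    x = table.values
    if pseudocount is None:
        pseudocount = 0.0
        if (x == 0).any():
            nz = x[x > 0]
            if nz.size == 0:
                raise ValueError("table is all zeros")
            pseudocount = float(nz.min()) / 2.0
    if (x == 0).any() and pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 when zeros are present")
    lx = np.log(x + pseudocount)
    sd = lx.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
        log.info("log_autoscale dropped %d constant features: %s",
                 len(dropped), dropped[:10])
    lx = lx[:, keep]
    z = (lx - lx.mean(axis=0)) / lx.std(axis=0, ddof=1)
    return z, [f for f, k in zip(table.feature_ids, keep) if k]
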