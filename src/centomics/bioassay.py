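"""Statistics for the wet-lab validation assays: Kaplan-Meier lifespan
analysis with the log-rank test and percent lifespan extension, CCK-8 cell
viability, and relative qPCR expression (2^-ddCt).

Survival estimation and the Mantel-Cox test are delegated to lifelines;
the module adds the input contract, the restricted-mean lifespan summary,
and the reporting conventions (two-decimal percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time


@dataclass
class SurvivalData:
    """Per-animal event records for one or more assay arms."""

    frame: pd.DataFrame  # columns: animal_id, arm, day, censored (0/1)

    def __post_init__(self) -> None:
        need = {"animal_id", "arm", "day", "censored"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"survival table missing columns {sorted(missing)}")
        if (self.frame["day"] <= 0).any():
            raise ValueError("event days must be positive")
        if not set(self.frame["censored"].unique()) <= {0, 1}:
            raise ValueError("censored must be 0/1")

    def arm(self, name: str) -> pd.DataFrame:
        sub = self.frame[self.frame["arm"] == name]
        if sub.empty:
            raise ValueError(f"arm {name!r} not present")
        return sub


@dataclass
class KmCurve:
    arm: str
    times: np.ndarray       # ordered event times
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    mean_lifespan: float    # restricted mean over the observed span


def read_survival_tsv(path: str | Path) -> SurvivalData:
    return SurvivalData(pd.read_csv(path, sep="\t"))


def km_estimate(data: SurvivalData, arm: str) -> KmCurve:
    """Product-limit estimate for one arm.

    Mean lifespan is the restricted mean (area under the curve up to the
    last observed time), which equals the arithmetic mean of event days
    when nothing is censored. All-censored arms have no defined mean and
    raise.
    """
    sub = data.arm(arm)
    events = 1 - sub["censored"].to_numpy()
    if events.sum() == 0:
        raise ValueError(f"arm {arm!r} has no events; mean lifespan undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["day"], event_observed=events)
    tmax = float(sub["day"].max())
    mean = float(restricted_mean_survival_time(kmf, t=tmax))
    event_times = np.sort(sub.loc[sub["censored"] == 0, "day"].unique().astype(float))
    surv = np.array([float(kmf.predict(t)) for t in event_times])
    ev_table = kmf.event_table
    at_risk = np.array([int(ev_table.loc[t, "at_risk"]) for t in event_times])
    return KmCurve(arm=arm, times=event_times, survival=surv,
                   at_risk=at_risk, mean_lifespan=mean)


def logrank_test(data: SurvivalData, arm_a: str, arm_b: str) -> tuple[float, float]:
    """Mantel-Cox log-rank test between two arms: (chi-square on 1 df, p)."""
    a, b = data.arm(arm_a), data.arm(arm_b)
    for name, sub in ((arm_a, a), (arm_b, b)):
        if (sub["censored"] == 0).sum() == 0:
            raise ValueError(f"arm {name!r} has no events")
    res = _ll_logrank(
        a["day"], b["day"],
        event_observed_A=1 - a["censored"], event_observed_B=1 - b["censored"],
    )
    return float(res.test_statistic), float(res.p_value)


def lifespan_extension_pct(mean_control: float, mean_treated: float) -> float:
    """Percent lifespan extension relative to control, two decimals."""
    if mean_control <= 0:
        raise ValueError("control mean lifespan must be positive")
    return round((mean_treated - mean_control) / mean_control * 100.0, 2)


def viability_pct(a_treated: float, a_blank: float, a_control: float) -> float:
    """CCK-8 cell viability: (A_treated - A_blank)/(A_control - A_blank) x 100."""
    if a_control == a_blank:
        raise ValueError("control and blank absorbance are equal")
    return (a_treated - a_blank) / (a_control - a_blank) * 100.0


def ddct_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^-ddCt with a reference gene."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
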