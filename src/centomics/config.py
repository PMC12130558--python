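"""Analysis configuration.

All thresholds used across the pipeline live in one flat config object that
round-trips through YAML unchanged, so a run is fully described by
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and switches shared by every pipeline stage.

    Parameters
    ----------
    alpha : float
        FDR / p-value threshold for univariate screens (default 0.05).
    vip_threshold_main : float
        VIP cut-off for the centenarian-vs-rest marker screen (default 1.5).
    vip_threshold_hcfc : float
        VIP cut-off for the healthy-vs-frail centenarian screen (default 1.0).
    lda_threshold_main : float
        Effect-size cut-off (log10, per-million scale) for the
        centenarian-vs-rest genus screen (default 3.0).
    lda_threshold_hcfc : float
        Effect-size cut-off for the healthy-vs-frail genus screen (default 2.0).
    prevalence_min : float
        Detection-prevalence filter: keep features present in strictly more
        than this fraction of samples (default 0.10).
    corr_r_min, corr_p_max : float
        Spearman edge filter for the metabolite-microbe network.
    fi_cut : int
        Frailty-index threshold splitting healthy (FI < cut) from frail
        (FI >= cut) centenarians (default 11).
    family_requires_control_sig : bool
        Strict longevity-family rule: relatives must also differ from both
        control groups (default True).
    prevalence_as_mean_abundance : bool
        Alternative reading of the ">10% relative abundance" filter as a mean
        relative-abundance cut instead of detection prevalence (default False).
    two_group_test : str
        "wilcoxon" (default) or "ttest" for two-group comparisons.
    n_components : int
        PLS-DA components fitted (default 2).
    n_permutations : int
        Label permutations for the PLS-DA overfitting check (default 99).
    seed : int
        Master seed for every stochastic stage.
    """

    alpha: float = 0.05
    vip_threshold_main: float = 1.5
    vip_threshold_hcfc: float = 1.0
    lda_threshold_main: float = 3.0
    lda_threshold_hcfc: float = 2.0
    prevalence_min: float = 0.10
    corr_r_min: float = 0.2
    corr_p_max: float = 0.05
    fi_cut: int = 11
    family_requires_control_sig: bool = True
    prevalence_as_mean_abundance: bool = False
    two_group_test: str = "wilcoxon"
    n_components: int = 2
    n_permutations: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 <= self.prevalence_min < 1:
            raise ValueError("prevalence_min must be in [0, 1)")
        if not 0 <= self.corr_r_min <= 1.01:
            raise ValueError("corr_r_min must be in [0, 1]")
        if not 0 < self.corr_p_max <= 1:
            raise ValueError("corr_p_max must be in (0, 1]")
        if self.fi_cut < 0:
            raise ValueError("fi_cut must be >= 0")
        if self.two_group_test not in ("wilcoxon", "ttest"):
            raise ValueError("two_group_test must be 'wilcoxon' or 'ttest'")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_permutations < 19:
            raise ValueError("n_permutations must be >= 19")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
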