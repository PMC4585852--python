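"""Run configuration: every tunable of the downstream stages, with defaults.

A single declarative YAML file holds all thresholds, permutation counts and
seeds, so that a pipeline run is fully determined by (config, input files).
Serialising and reloading a config yields an identical object.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class CNAParams:
    """Segmentation, re-centering, calling and recurrence tunables."""

    alpha: float = 0.01          # per-split permutation significance
    min_probes: int = 3          # smallest admissible segment
    n_perm_split: int = 100      # permutations per candidate split
    mad_k: float = 4.0           # outlier winsorization at k*MAD
    smooth_window: int = 5       # neighbourhood for outlier smoothing
    kde_bandwidth: float = 0.1   # re-centering mode search (log2 units)
    t_loss: float = 0.2          # segment mean < -t_loss -> loss
    t_gain: float = 0.2          # segment mean > t_gain -> gain
    t_amp: float = 1.0           # segment mean > t_amp -> amplification
    min_recurrence: int = 3      # lines sharing a direction
    n_perm_recurrence: int = 500
    recurrence_fdr: float = 0.05
    seed: int = 101


@dataclass
class ExpressionParams:
    above_background_frac: float = 0.25
    good_spot_frac: float = 0.75
    quartile_method: str = "linear"  # numpy interpolation convention, pinned
    kmeans_k: int = 3
    kmeans_n_init: int = 10
    seed: int = 202


@dataclass
class DiffRepParams:
    rp_n_perm: int = 1000
    rp_pfp_threshold: float = 0.05
    t_q_threshold: float = 0.05
    sam_n_perm: int = 200
    sam_fdr_threshold: float = 0.05
    seed: int = 303


@dataclass
class RestoreParams:
    wilcoxon_adjust: bool = False  # BH across lines, off by default
    n_boot: int = 1000
    seed: int = 404


@dataclass
class StoichiometryParams:
    n_boot: int = 1000
    seed: int = 505


@dataclass
class PrognosisParams:
    alpha: float = 0.05
    adjust: bool = False
    seed: int = 606


@dataclass
class RunConfig:
    """All tunables of the analysis stages; see section dataclasses."""

    cna: CNAParams = field(default_factory=CNAParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    diffrep: DiffRepParams = field(default_factory=DiffRepParams)
    restore: RestoreParams = field(default_factory=RestoreParams)
    stoichiometry: StoichiometryParams = field(default_factory=StoichiometryParams)
    prognosis: PrognosisParams = field(default_factory=PrognosisParams)
    provenance: str = ""

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if isinstance(v, dict) and f.name != "provenance":
                section_cls = {
                    "cna": CNAParams,
                    "expression": ExpressionParams,
                    "diffrep": DiffRepParams,
                    "restore": RestoreParams,
                    "stoichiometry": StoichiometryParams,
                    "prognosis": PrognosisParams,
                }[f.name]
                kwargs[f.name] = section_cls(**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def reseed(self, seed: int) -> "RunConfig":
        """Derive per-stage seeds deterministically from one master seed."""
        cfg = RunConfig.from_dict(self.to_dict())
        for i, section in enumerate(
            (cfg.cna, cfg.expression, cfg.diffrep, cfg.restore,
             cfg.stoichiometry, cfg.prognosis)
        ):
            section.seed = (seed * 1000 + i) % (2**31 - 1)
        return cfg
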