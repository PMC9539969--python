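"""Pipeline configuration: every numeric parameter of every stage.

Defaults are the published analysis settings (filter edges 3-300 Hz, order
2, 50 Hz notch, +/-900 ms epochs, 10 ms baseline, 1 SD detection threshold,
1-9/5-20 ms windows, 45-55% onset band, CoV threshold 1.0, 20% inclusion,
10,000 permutations, alpha 0.05).  A config round-trips losslessly through
YAML, and its hash stamps every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_subjects: int = 15
    session_paths: tuple[str, ...] = ()     # if set, load instead of simulate
    # signal_prep
    pre_ms: float = 900.0
    post_ms: float = 900.0
    band_Hz: tuple[float, float] = (3.0, 300.0)
    filter_order: int = 2
    notch_Hz: float = 50.0
    notch_q: float = 30.0
    zero_phase: bool = True
    baseline_ms: tuple[float, float] = (-10.0, 0.0)
    # evoked_peaks
    baseline_sd_ms: tuple[float, float] = (-100.0, 0.0)
    p1_window_ms: tuple[float, float] = (1.0, 9.0)
    n1_window_ms: tuple[float, float] = (5.0, 20.0)
    detection_threshold_sd: float = 1.0
    onset_band: tuple[float, float] = (0.45, 0.55)
    adaptive_trial_window: bool = False
    # dose_response
    cov_threshold: float = 1.0
    min_session_fraction: float = 0.2
    n_bootstrap: int = 2000
    # perm_stats
    n_permutations: int = 10_000
    alpha: float = 0.05
    stats_engine: str = "fast"
    stratified_permutation: bool = True
    # orchestration
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if not isinstance(sim, SimulationConfig):
            sim = SimulationConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
            })
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name == "simulation" or f_.name not in d:
                continue
            v = d[f_.name]
            kwargs[f_.name] = tuple(v) if isinstance(v, list) else v
        return cls(simulation=sim, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
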