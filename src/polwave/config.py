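"""Run configuration: YAML-backed parameters for the full pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import ConfigError
from .simulate import SimulationConfig


@dataclass
class RunConfig:
    """Parameters of an end-to-end run (simulate -> apa -> elongate -> chip).

    ``simulation`` carries the generator design; the remaining fields are
    the analysis knobs with their documented defaults.  Round-trips
    losslessly through YAML via :meth:`to_yaml` / :meth:`from_yaml`.
    """

    out_dir: str = "polwave_run"
    seed: int = 0
    # apa
    pas_window: int = 50
    tau: float = 1.5
    min_pas: int = 2
    min_distal_reads: int = 5
    proximal_policy: str = "sum_upstream"
    expression_fold: float = 1.5
    # elongation
    bin_size: int = 200
    min_rpm: float = 100.0
    min_first_peak_kb: float = 2.0
    min_gene_width: int = 60_000
    max_gene_width: int = 300_000
    window_upstream: int = 2_000
    window_downstream: int = 120_000
    # chip peaks
    peak_window: int = 500
    peak_step: int = 100
    p_cutoff: float = 1e-5
    tss_window: int = 1_000
    make_plots: bool = False  # QC figures; excluded from the determinism manifest
    simulation: dict = field(default_factory=dict)

    def sim_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        try:
            return SimulationConfig(**sim)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if self.pas_window < 0:
            raise ConfigError("pas_window must be >= 0")
        if self.tau <= 1:
            raise ConfigError("tau must be > 1")
        if self.peak_window < self.peak_step:
            raise ConfigError("peak_window must be >= peak_step")
        if not (0 < self.p_cutoff < 1):
            raise ConfigError("p_cutoff must be in (0, 1)")
        self.sim_config()  # raises on bad simulation block

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def require_paths(*paths) -> None:
    """Validate that every referenced input exists before any computation."""
    missing = [str(p) for p in paths if p is not None and not Path(p).exists()]
    if missing:
        raise ConfigError(f"missing input file(s): {', '.join(missing)}")
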