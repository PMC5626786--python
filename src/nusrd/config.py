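"""Run configuration: a YAML-serializable bundle of all stage parameters."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


def _default_nu():
    return [25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 750.0, 1000.0]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    seed: int = 0
    out_dir: str = "nusrd_out"
    # system
    template: str = "sh3_like"
    n_sites: int = 14
    ndim: int = 2
    nucleus: str = "15N"
    kex: float = 182.0
    p_b: float = 0.029
    dw_range_ppm: list = field(default_factory=lambda: [0.2, 3.0])
    # series
    nu_hz: list = field(default_factory=_default_nu)
    t_relax: float = 0.04
    field_tesla: float = 18.8
    # grid
    n_direct: int = 64
    sw_direct_hz: float = 900.0
    n_indirect: list = field(default_factory=lambda: [48])
    sw_indirect_hz: list = field(default_factory=lambda: [2250.0])
    # noise / sampling
    target_sigma_r2: float = 0.2
    nus_fraction: float = 0.25
    t_match: float = 0.1
    coupled_schedule: bool = False
    # reconstruction
    method: str = "comdd"            # comdd | irls_ve | full_ft
    n_components: int = 0            # 0 -> n_sites + 2
    lambda_reg: float = 1e-4
    comdd_iter: int = 2000
    comdd_tol: float = 1e-9
    irls_iter: int = 30
    irls_p: float = 0.5
    # errors
    jackknife_trials: int = 20
    jackknife_d_frac: float = 0.175
    # fitting
    alpha: float = 0.01
    fit_starts: int = 10
    exclude_overlapped: bool = True   # drop peaks closer than ~2.5 linewidths
    # targeted acquisition
    ta_steps: list = field(default_factory=lambda: [0.033, 0.043, 0.053, 0.063, 0.073, 0.083])
    ta_realizations: int = 15
    ta_target_sigma: float = 0.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration (logged with every run)."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
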