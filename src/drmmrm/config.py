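"""Run configuration: YAML round trip and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .design import ARM_CONFIGS, DEFAULT_ED50_GRID, TIMECOURSES, Design, scenario_grid

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a study run."""

    n_per_arm: int = 39
    baseline_mean: float = 5.63
    omega: float = 0.3716
    sigma: float = 0.50
    rho: float = 0.226
    ed50_values: list = field(default_factory=lambda: list(DEFAULT_ED50_GRID))
    timecourses: list = field(default_factory=lambda: list(TIMECOURSES))
    arm_config: str = "4dose"
    methods: list = field(default_factory=lambda: ["MMRM", "DR-EOS", "DR-MMRM"])
    n_reps: int = 1000
    seed: int = 0
    out_dir: str = "study_out"
    resume: bool = False

    def __post_init__(self) -> None:
        if self.arm_config not in ARM_CONFIGS:
            raise ValueError(f"unknown arm_config {self.arm_config!r}")
        bad_tc = set(self.timecourses) - set(TIMECOURSES)
        if bad_tc:
            raise ValueError(f"unknown timecourses: {sorted(bad_tc)}")
        self.design()  # triggers Design invariant checks

    def design(self) -> Design:
        return Design(
            n_per_arm=self.n_per_arm,
            baseline_mean=self.baseline_mean,
            omega=self.omega,
            sigma=self.sigma,
            rho=self.rho,
        ).with_active_doses(ARM_CONFIGS[self.arm_config])

    def scenarios(self):
        return scenario_grid(
            ed50_values=self.ed50_values,
            timecourses=self.timecourses,
            arm_configs=[self.arm_config],
            n_reps=self.n_reps,
            master_seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config, applying keyword overrides (None ignored)."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
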