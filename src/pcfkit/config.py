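"""Run configuration: typed parameters, YAML loading, full validation.

Validation collects every violation (unknown keys, out-of-domain values)
instead of failing on the first, so a user fixes a config in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


@dataclass
class RunConfig:
    seed: int = 42
    mode: str = "simulate"  # simulate | real-input

    # ancestor / rearrangement plan
    n_chromosomes: int = 5
    chrom_bp: int = 4_000_000
    mshsb_per_chrom: int = 1
    mshsb_bp: int = 1_800_000
    n_inversions: int = 10
    n_fusions: int = 3
    n_fissions: int = 2

    # shredding / coverage
    mean_scaffold_bp: int = 1_000_000
    chimera_rate: float = 0.1
    n_pairs: int = 60_000
    insert_mean: float = 3_000.0
    insert_sd: float = 300.0
    p_chim_zero: float = 0.9

    # feature tracks
    cne_density_mshsb: float = 0.11
    cne_density_background: float = 0.02
    desert_halfwidth_bp: int = 50_000

    # probes
    probe_spacing_bp: int = 500_000
    probe_position_noise_sd: float = 0.0

    # synteny / PCF
    resolution: int = 150_000
    min_block_bp: int = 5_000
    block_bp: int = 40_000
    edge_erosion_bp: int = 5_000
    threshold_c: int | str = "calibrate"
    w_ref: float = 1.0
    w_out: float = 1.0
    w_read: float = 1.0
    join_min: float = 2.0
    coverage_mode: str = "min"

    # statistics
    window_bp: int = 1_000
    te_window_bp: int = 10_000
    alpha: float = 0.05

    # paths (real-input mode)
    blocks_path: str | None = None
    outgroup_blocks_path: str | None = None
    pairs_path: str | None = None
    cne_path: str | None = None
    te_path: str | None = None
    probe_map_path: str | None = None
    verification_results_path: str | None = None

    def weights(self) -> dict:
        return {"w_ref": self.w_ref, "w_out": self.w_out, "w_read": self.w_read}


_DOMAINS = {
    "mode": lambda v: v in ("simulate", "real-input"),
    "chimera_rate": lambda v: 0.0 <= v <= 1.0,
    "p_chim_zero": lambda v: 0.0 <= v <= 1.0,
    "cne_density_mshsb": lambda v: 0.0 <= v <= 1.0,
    "cne_density_background": lambda v: 0.0 <= v <= 1.0,
    "alpha": lambda v: 0.0 < v < 1.0,
    "insert_mean": lambda v: v > 0,
    "resolution": lambda v: v > 0,
    "probe_spacing_bp": lambda v: v > 0,
    "desert_halfwidth_bp": lambda v: v >= 0,
    "coverage_mode": lambda v: v in ("midpoint", "min"),
    "threshold_c": lambda v: v == "calibrate" or (isinstance(v, int) and v >= 0),
}

_POSITIVE_INTS = (
    "n_chromosomes", "chrom_bp", "mshsb_bp", "mean_scaffold_bp", "n_pairs",
    "min_block_bp", "block_bp", "window_bp", "te_window_bp", "seed",
)


def validate_config(raw: str | dict | Path) -> RunConfig:
    """Parse and validate a config mapping or YAML text/path.

    Raises :class:`ConfigError` listing *all* violations at once.
    """
    if isinstance(raw, Path) or (isinstance(raw, str) and "\n" not in raw and raw.endswith((".yaml", ".yml"))):
        raw = Path(raw).read_text()
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    known = {f.name for f in fields(RunConfig)}
    problems = [f"unknown key: {key}" for key in sorted(set(raw) - known)]

    cfg = RunConfig()
    for key, value in raw.items():
        if key in known:
            setattr(cfg, key, value)

    for key, check in _DOMAINS.items():
        value = getattr(cfg, key)
        try:
            ok = check(value)
        except TypeError:
            ok = False
        if not ok:
            problems.append(f"{key}: value {value!r} out of domain")
    for key in _POSITIVE_INTS:
        value = getattr(cfg, key)
        if not (isinstance(value, int) and value > 0):
            problems.append(f"{key}: must be a positive integer, got {value!r}")
    if problems:
        raise ConfigError(problems)
    return cfg
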