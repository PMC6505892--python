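"""Run configuration: every tunable of the pipeline with validated defaults.

Config files are flat ``key = value`` lines with dotted namespaces
(``distance.beta0 = 1.448``); command-line overrides take precedence over
file values.  Unknown keys are rejected with a nearest-match suggestion.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .distance import DEFAULT_BETA0, DEFAULT_BETA1, DEFAULT_BIN_EDGES


def _default_c_grid():
    return tuple(2.0**e for e in range(-3, 8, 2))  # 2^-3 .. 2^7


def _default_gamma_grid():
    return tuple(2.0**e for e in range(-7, 4, 2))  # 2^-7 .. 2^3


@dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05  # t-test pattern-selection threshold
    motif_p_threshold: float = 1e-4  # per-occurrence scan p-value cutoff
    weighting: str = "multiply"  # multiply | append | none
    motif_dis_mode: str = "tls"  # tls | insertion
    beta0: float = DEFAULT_BETA0
    beta1: float = DEFAULT_BETA1
    refit_distance: bool = True
    pn_ratio: float = 1.0
    window_bp: int = 30_000
    bin_edges: tuple = DEFAULT_BIN_EDGES
    svm_c_grid: tuple = field(default_factory=_default_c_grid)
    svm_gamma_grid: tuple = field(default_factory=_default_gamma_grid)
    inner_folds: int = 3
    cv_folds: int = 5

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.motif_p_threshold <= 1:
            raise ValueError("motif_p_threshold must be in (0,1]")
        if self.weighting not in ("multiply", "append", "none"):
            raise ValueError(
                f"weighting must be multiply/append/none, got {self.weighting!r}"
            )
        if self.motif_dis_mode not in ("tls", "insertion"):
            raise ValueError("motif_dis_mode must be 'tls' or 'insertion'")
        if self.pn_ratio <= 0:
            raise ValueError("pn_ratio must be positive")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.inner_folds < 2 or self.cv_folds < 2:
            raise ValueError("fold counts must be at least 2")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2^31)")


# dotted config-file key -> RunConfig attribute
KEY_MAP = {
    "seed": "seed",
    "pattern.alpha": "alpha",
    "motif.p_threshold": "motif_p_threshold",
    "motif.dis_mode": "motif_dis_mode",
    "distance.beta0": "beta0",
    "distance.beta1": "beta1",
    "distance.weighting": "weighting",
    "distance.refit": "refit_distance",
    "train.pn_ratio": "pn_ratio",
    "predict.window": "window_bp",
    "layer1.inner_folds": "inner_folds",
    "evaluate.cv_folds": "cv_folds",
}


def _coerce(attr: str, raw: str):
    current = getattr(RunConfig(), attr)
    if isinstance(current, bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional file plus override mapping."""
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in KEY_MAP:
                hint = difflib.get_close_matches(key, KEY_MAP, n=1)
                suffix = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ValueError(f"unknown config key {key!r}{suffix}")
            values[KEY_MAP[key]] = _coerce(KEY_MAP[key], raw)
    valid_attrs = {f.name for f in fields(RunConfig)}
    for key, val in (overrides or {}).items():
        attr = KEY_MAP.get(key, key)
        if attr not in valid_attrs:
            hint = difflib.get_close_matches(
                key, list(KEY_MAP) + sorted(valid_attrs), n=1
            )
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")
        values[attr] = val
    return RunConfig(**values)
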