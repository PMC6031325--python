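"""Analysis configuration: one record holding every tunable parameter.

Defaults are the standard parameters of the assay where they exist
(120 nm line thickness, 20% ratio-variation threshold, 0.5 mm minimum
analyzed length, 2 µm colocalization cutoff, 30 nm pixels); the remainder
are documented implementation choices (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    pixel_size_nm: float = 30.0
    line_thickness_nm: float = 120.0
    ratio_threshold: float = 0.20
    epsilon_frac: float = 0.01
    min_run_samples: int = 5
    smoothing_window: int = 5
    cutoff_um: float = 2.0
    background_radius_px: int = 50
    min_total_length_um: float = 500.0
    step_um: float | None = None  # None -> one pixel
    min_path_length_um: float = 1.0
    ridge_sigma_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "pixel_size_nm",
            "line_thickness_nm",
            "ratio_threshold",
            "cutoff_um",
            "background_radius_px",
            "min_total_length_um",
            "min_path_length_um",
            "ridge_sigma_px",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon_frac < 0:
            raise ValueError("epsilon_frac must be >= 0")
        if self.min_run_samples < 1 or self.smoothing_window < 1:
            raise ValueError("min_run_samples and smoothing_window must be >= 1")
        if self.step_um is not None and self.step_um <= 0:
            raise ValueError("step_um must be positive (or None)")

    @property
    def effective_step_um(self) -> float:
        return self.step_um if self.step_um is not None else self.pixel_size_nm / 1000.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def hash(self) -> str:
        """Short digest of the canonical config, stamped into every output."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
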