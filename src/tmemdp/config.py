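"""Run configuration: one YAML file bundling every tunable parameter.

The morphometric thresholds *are* the algorithm, so every report echoes the
effective configuration and its hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .morphometry import MorphometryParams
from .scoring import RiskParams, ScoringParams
from .slide_io import CalibrationParams
from .stain_features import DEFAULT_STAIN_COLORS, StainMatrix

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All parameters of one scoring run."""

    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    risk: RiskParams = field(default_factory=RiskParams)
    stain_colors: dict = field(default_factory=lambda: dict(DEFAULT_STAIN_COLORS))
    median_radius: int = 1
    classifier_path: str | None = None
    verbosity: int = 1

    def stain_matrix(self) -> StainMatrix:
        return StainMatrix.from_colors(
            {k: tuple(v) for k, v in self.stain_colors.items()}
        )

    def to_dict(self) -> dict:
        return {
            "calibration": asdict(self.calibration),
            "morphometry": asdict(self.morphometry),
            "scoring": asdict(self.scoring),
            "risk": asdict(self.risk),
            "stain_colors": {k: list(v) for k, v in self.stain_colors.items()},
            "median_radius": self.median_radius,
            "classifier_path": self.classifier_path,
            "verbosity": self.verbosity,
        }

    def hash(self) -> str:
        """Stable hash of the effective parameters (for report provenance)."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {
            "calibration",
            "morphometry",
            "scoring",
            "risk",
            "stain_colors",
            "median_radius",
            "classifier_path",
            "verbosity",
        }
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, key):
            section = dict(data.get(key, {}))
            valid = set(klass.__dataclass_fields__)
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in '{key}': {sorted(bad)}")
            return klass(**section)

        return cls(
            calibration=build(CalibrationParams, "calibration"),
            morphometry=build(MorphometryParams, "morphometry"),
            scoring=build(ScoringParams, "scoring"),
            risk=build(RiskParams, "risk"),
            stain_colors={
                k: tuple(v)
                for k, v in data.get("stain_colors", DEFAULT_STAIN_COLORS).items()
            },
            median_radius=int(data.get("median_radius", 1)),
            classifier_path=data.get("classifier_path"),
            verbosity=int(data.get("verbosity", 1)),
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; with no path, return the defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
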