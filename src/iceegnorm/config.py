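"""Shared pipeline configuration.

Defaults reproduce the standard analysis constants: 0.5–80 Hz band-pass,
200 Hz target rate, 2 s / 1 s Welch windows, five bands with the γ
power-line exclusions, 5 mm assignment distance, bilateral subcortical
exclusions, 95% confidence level.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from typing import List, Sequence, Tuple

import yaml

from .bands import STANDARD_BANDS, BandDefinition
from .cohort import DEFAULT_SUBCORTICAL_EXCLUSIONS


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with standard defaults."""

    # signal processing
    filter_low_hz: float = 0.5
    filter_high_hz: float = 80.0
    target_fs_hz: float = 200.0
    welch_window_s: float = 2.0
    welch_overlap_s: float = 1.0
    segment_length_s: float = 70.0
    ictal_gap_s: float = 7200.0
    # channel screening (heuristic approximation of visual review)
    flat_range_uv: float = 1.0
    amplitude_z: float = 5.0
    line_ratio: float = 3.0
    line_freqs: Tuple[float, ...] = (50.0, 60.0)
    # localisation
    max_assignment_mm: float = 5.0
    # table construction
    subcortical_exclusions: Tuple[str, ...] = DEFAULT_SUBCORTICAL_EXCLUSIONS
    mirror_rule: str = "mean"
    # modelling
    selection_alpha: float = 0.05
    ci_level: float = 0.95
    ci_method: str = "profile"
    regional_ci_method: str = "wald"
    singular_tol: float = 1e-4
    min_regional_rows: int = 10
    include_interaction: bool = False
    # deviation scoring
    score_denominator: str = "residual"
    score_threshold: float = 2.0
    # randomness
    seed: int = 0

    @property
    def bands(self) -> Sequence[BandDefinition]:
        return STANDARD_BANDS

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("line_freqs", "subcortical_exclusions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        """Stable short hash of the configuration, for run logs."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
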