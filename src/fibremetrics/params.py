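"""Parameter file handling.

A run is controlled by a flat ``key = value`` text file so that parameter
sets diff cleanly and can be archived next to results for provenance.  All
keys are optional; absent keys take the documented defaults.  The same keys
are accepted as CLI flags, which take precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["ParameterSet", "load_parameters", "save_parameters", "parameter_template"]


@dataclass
class ParameterSet:
    """All user-facing pipeline parameters.

    Suggested starting values are the defaults below; empirical refinement
    on a subset of images is advised.  Line width and curvature window
    should reflect the dominant filament thickness and curvature scale of
    the images.
    """

    contrast_saturation_pct: float = 0.35
    line_width_min_px: float = 5.0
    line_width_max_px: float = 5.0
    min_branch_px: float = 10.0
    curvature_window_min_px: int = 40
    curvature_window_max_px: int = 40
    curvature_window_step_px: int = 10
    min_gap_diameter_px: float = 10.0
    hdm_threshold: int = 185
    dark_lines: bool = False
    gap_analysis: bool = False
    contrast_high: float | None = None
    contrast_low: float | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        checks = [
            ("line_width_min_px", "line_width_max_px"),
            ("curvature_window_min_px", "curvature_window_max_px"),
        ]
        for lo, hi in checks:
            if getattr(self, lo) > getattr(self, hi):
                raise ValueError(f"{lo} ({getattr(self, lo)}) exceeds {hi} ({getattr(self, hi)})")
        if (
            self.contrast_low is not None
            and self.contrast_high is not None
            and self.contrast_low > self.contrast_high
        ):
            raise ValueError("contrast_low exceeds contrast_high")
        for name in ("contrast_saturation_pct",):
            if not 0 <= getattr(self, name) < 100:
                raise ValueError(f"{name} must lie in [0, 100)")
        if self.min_gap_diameter_px <= 0:
            raise ValueError("min_gap_diameter_px must be positive")
        if not 0 <= self.hdm_threshold <= 255:
            raise ValueError("hdm_threshold must lie in [0, 255]")


_BOOL_KEYS = {"dark_lines", "gap_analysis"}
_INT_KEYS = {
    "curvature_window_min_px",
    "curvature_window_max_px",
    "curvature_window_step_px",
    "hdm_threshold",
}
_OPTIONAL_KEYS = {"contrast_high", "contrast_low", "pixel_size_um"}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key in _OPTIONAL_KEYS and raw.lower() in {"", "none", "auto"}:
        return None
    if key in _BOOL_KEYS:
        if raw.lower() in {"true", "yes", "1"}:
            return True
        if raw.lower() in {"false", "no", "0"}:
            return False
        raise ValueError(f"cannot parse boolean for {key!r}: {raw!r}")
    if key in _INT_KEYS:
        return int(float(raw))
    return float(raw)


def load_parameters(path: str | Path) -> ParameterSet:
    """Parse and validate a ``key = value`` parameter file.

    Unknown keys produce a warning and are ignored; ``#`` starts a comment.
    """
    path = Path(path)
    known = {f.name for f in fields(ParameterSet)}
    values: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in known:
            warnings.warn(f"{path}:{lineno}: unknown parameter {key!r} ignored", stacklevel=2)
            continue
        values[key] = _parse_value(key, raw)
    return ParameterSet(**values)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a ``key = value`` file (round-trips exactly)."""
    lines = []
    for f in fields(ParameterSet):
        v = getattr(params, f.name)
        lines.append(f"{f.name} = {'none' if v is None else v}")
    Path(path).write_text("\n".join(lines) + "\n")


def parameter_template() -> str:
    """A commented parameter file with the suggested starting values."""
    p = ParameterSet()
    doc = {
        "contrast_saturation_pct": "percent of pixels clipped by the contrast stretch",
        "line_width_min_px": "smallest fibre thickness to detect (px)",
        "line_width_max_px": "largest fibre thickness; sweeps in increments of 5",
        "min_branch_px": "terminal branches shorter than this are pruned (px)",
        "curvature_window_min_px": "smallest curvature window (px)",
        "curvature_window_max_px": "largest curvature window (px)",
        "curvature_window_step_px": "step between curvature windows (px)",
        "min_gap_diameter_px": "smallest gap circle diameter reported (px)",
        "hdm_threshold": "high-density-matrix threshold on the 8-bit scale",
        "dark_lines": "true when fibres are dark on a light background",
        "gap_analysis": "enable inscribed-circle gap analysis",
        "contrast_high": "absolute ridge-response seed threshold (auto by default)",
        "contrast_low": "absolute ridge-response growth threshold (auto by default)",
        "pixel_size_um": "um per pixel; lengths reported in um when set",
    }
    lines = ["# fibremetrics parameter file (key = value; '#' comments)"]
    for f in fields(ParameterSet):
        v = getattr(p, f.name)
        lines.append(f"{f.name} = {'none' if v is None else v}  # {doc[f.name]}")
    return "\n".join(lines) + "\n"
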