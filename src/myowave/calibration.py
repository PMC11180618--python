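"""Acquisition calibration: frame rate, spatial scale, horn orientation.

The defaults describe a stereo-microscope time-lapse of a pinned mouse
uterine horn: 5 frames per second and 110.85 pixels per millimetre. The
``orientation`` field records which image edge holds the oviductal end of
the horn so that the sign of a wave's slope on a spatiotemporal map can be
read as "toward the cervix" or "toward the oviduct".
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import ValidationError

ORIENTATIONS = ("left", "right")


@dataclass(frozen=True)
class CalibrationConfig:
    """Physical calibration of a recording.

    Parameters
    ----------
    fps
        Frames per second of the acquisition (> 0).
    px_per_mm
        Pixels per millimetre along the horn axis (> 0).
    orientation
        Which image edge is the oviductal end: ``"left"`` or ``"right"``.
        Maps are stored oviduct-first, so a recording with the oviduct on
        the right is flipped at map construction.
    """

    fps: float = 5.0
    px_per_mm: float = 110.85
    orientation: str = "left"

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if not self.px_per_mm > 0:
            raise ValidationError(f"px_per_mm must be > 0, got {self.px_per_mm}")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )

    @property
    def um_per_px(self) -> float:
        """Micrometres spanned by one pixel."""
        return 1000.0 / self.px_per_mm

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        return cls(**{k: d[k] for k in ("fps", "px_per_mm", "orientation") if k in d})
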