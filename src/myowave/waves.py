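"""Waveform metrics from annotated contraction waves (pipeline step 3).

A travelling contraction appears on a spatiotemporal map as a diagonal
band. An annotation marks one wave: a ridge segment traced along the
band's crest, the band's spatial extent at a reference frame, and the
frame at which the *next* wave's crest passes the ridge's starting
column. From these, in physical units:

velocity   = |ridge slope|, micrometres per second;
direction  = sign of the slope on the oviduct-left axis
             (positive -> toward the cervix);
amplitude  = spatial extent of the band, micrometres;
period     = time to the next crest at a fixed position, seconds;
frequency  = 1 / period, hertz;
wavelength = velocity / frequency, micrometres.

Frequency and wavelength are definitional identities of period and
velocity, exact by construction. Waves without an annotated successor
carry velocity/amplitude/direction only.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from .calibration import CalibrationConfig
from .errors import DegenerateAnnotationError, ValidationError

DIRECTIONS = ("toward_cervix", "toward_oviduct", "stationary")

#: Below this speed a wave is reported as stationary (manual ridge
#: placement cannot resolve slower drift).
STATIONARY_FLOOR_UM_S = 0.1


def px_to_mm(d: float, cal: CalibrationConfig) -> float:
    """Convert a pixel distance to millimetres."""
    return d / cal.px_per_mm


def frames_to_s(f: float, cal: CalibrationConfig) -> float:
    """Convert a frame count to seconds."""
    return f / cal.fps


@dataclass(frozen=True)
class WaveAnnotation:
    """A manually marked contraction wave on a spatiotemporal map.

    ``ridge``: two ``(column, frame)`` endpoints along the wave crest
    (fractional values allowed). ``band_extent``: two columns marking
    the spatial width of the band at a reference frame.
    ``next_ridge_frame``: frame at which the next successive crest
    passes the ridge's starting column; ``None`` when the wave has no
    annotated successor.
    """

    ridge: tuple[tuple[float, float], tuple[float, float]]
    band_extent: tuple[float, float]
    next_ridge_frame: float | None = None
    map_id: str = ""

    def __post_init__(self) -> None:
        (c0, t0), (c1, t1) = self.ridge
        if t0 == t1:
            raise DegenerateAnnotationError(
                "ridge endpoints share a frame; a wave must span time"
            )
        if self.band_extent[0] > self.band_extent[1]:
            raise ValidationError(
                f"band_extent columns must be ordered, got {self.band_extent}"
            )
        if self.next_ridge_frame is not None and self.next_ridge_frame <= min(t0, t1):
            raise ValidationError(
                "next_ridge_frame must come after the ridge's starting frame"
            )

    @property
    def midpoint_column(self) -> float:
        return 0.5 * (self.ridge[0][0] + self.ridge[1][0])


@dataclass
class WaveMetrics:
    """Physical-unit metrics of one wave (fields None when unmeasurable)."""

    amplitude_um: float
    velocity_um_s: float
    direction: str
    period_s: float | None = None
    frequency_hz: float | None = None
    wavelength_um: float | None = None
    segment: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        for name in ("amplitude_um", "velocity_um_s", "period_s",
                     "frequency_hz", "wavelength_um"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    def to_dict(self) -> dict:
        return {
            "amplitude_um": self.amplitude_um,
            "period_s": self.period_s,
            "frequency_hz": self.frequency_hz,
            "velocity_um_s": self.velocity_um_s,
            "wavelength_um": self.wavelength_um,
            "direction": self.direction,
            "segment": self.segment,
        }


def compute_metrics(
    ann: WaveAnnotation,
    cal: CalibrationConfig | None = None,
    stationary_floor_um_s: float = STATIONARY_FLOOR_UM_S,
) -> WaveMetrics:
    """Convert one annotation into :class:`WaveMetrics`.

    Velocity is the absolute ridge slope (pixels/frame) converted to
    micrometres per second; direction comes from the slope's sign on the
    oviduct-left axis, with speeds below ``stationary_floor_um_s``
    reported as stationary. Period-dependent fields are computed only
    when ``next_ridge_frame`` is present.
    """
    cal = cal or CalibrationConfig()
    (c0, t0), (c1, t1) = ann.ridge
    slope = (c1 - c0) / (t1 - t0)  # px / frame, sign meaningful
    velocity = abs(slope) * cal.um_per_px * cal.fps  # um / s

    if velocity < stationary_floor_um_s:
        direction = "stationary"
    elif slope > 0:
        direction = "toward_cervix"
    else:
        direction = "toward_oviduct"

    amplitude = abs(ann.band_extent[1] - ann.band_extent[0]) * cal.um_per_px

    period = frequency = wavelength = None
    if ann.next_ridge_frame is not None:
        start_frame = min(t0, t1)
        period = frames_to_s(ann.next_ridge_frame - start_frame, cal)
        frequency = 1.0 / period
        wavelength = velocity / frequency

    return WaveMetrics(
        amplitude_um=amplitude,
        velocity_um_s=velocity,
        direction=direction,
        period_s=period,
        frequency_hz=frequency,
        wavelength_um=wavelength,
    )


_METRIC_FIELDS = ("amplitude_um", "period_s", "frequency_hz",
                  "velocity_um_s", "wavelength_um")


def summarize(metrics: list[WaveMetrics]) -> dict:
    """Per-horn summary: median and count of each metric over present values.

    The last wave in a recording often lacks a successor and hence a
    period; counts are therefore tracked per metric, not per wave.
    """
    if not metrics:
        raise ValidationError("cannot summarize an empty metrics list")
    out: dict = {"n_waves": len(metrics)}
    for name in _METRIC_FIELDS:
        vals = [getattr(m, name) for m in metrics if getattr(m, name) is not None]
        out[name] = {"median": median(vals) if vals else None, "n": len(vals)}
    return out
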