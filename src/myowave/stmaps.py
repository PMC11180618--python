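"""Spatiotemporal (Hovmöller) maps (pipeline step 2).

A spatiotemporal map collapses each frame to one value per column along
the horn — the pixel distance between the two boundaries ("area", a
proxy for local tube diameter seen by the circular muscle) or the mean
fluorescence intensity between them (responsive to both circular and
longitudinal contraction, because compressed tissue concentrates the
reporter). Travelling contractions appear as diagonal bands whose slope
is the wave velocity.

The *enhanced* form highlights those bands: a Sobel gradient magnitude
on the space x time matrix detects change, a wide centred moving average
along space removes the horn's static thickness/intensity profile, and
a short moving average along time suppresses residual noise.

The spatial axis of every map runs oviduct -> cervix; recordings with
the oviduct on the right are flipped at construction, so a positive
band slope always means "toward the cervix".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.ndimage import convolve1d

from .boundary import HornBoundaries, sobel_kernels
from .calibration import CalibrationConfig
from .errors import FrameSizeError, ValidationError
from .video_io import FrameStack

MAP_QUANTITIES = ("area_px", "mean_intensity", "enhanced_area", "enhanced_intensity")


@dataclass
class SpatioTemporalMap:
    """Space x time matrix of a per-column quantity.

    ``values[c, t]``: column ``c`` along the horn (oviduct first), frame
    ``t``. Invalid cells are NaN; ``mask`` exposes them as booleans.
    """

    values: np.ndarray
    quantity: str
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"map values must be 2D, got {self.values.shape}")
        if self.quantity not in MAP_QUANTITIES:
            raise ValidationError(
                f"quantity must be one of {MAP_QUANTITIES}, got {self.quantity!r}"
            )
        v = self.values[np.isfinite(self.values)]
        if self.quantity == "area_px" and v.size and v.min() < 0:
            raise ValidationError("area values must be >= 0")
        if self.quantity == "mean_intensity" and v.size and (
            v.min() < 0 or v.max() > 255
        ):
            raise ValidationError("mean intensity must lie within [0, 255]")

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is invalid."""
        return ~np.isfinite(self.values)

    @property
    def n_columns(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EnhanceParams:
    """Parameters of the map-enhancement pipeline.

    ``change_kernel``: Sobel aperture on the map. ``spatial_detrend_window``:
    width (columns) of the moving average subtracted along space.
    ``temporal_lowpass_window``: width (frames) of the final moving
    average along time. All odd; the detrend window must exceed the
    low-pass window so the two filters act at separated scales.
    """

    change_kernel: int = 5
    spatial_detrend_window: int = 51
    temporal_lowpass_window: int = 5

    def __post_init__(self) -> None:
        for name in ("change_kernel", "spatial_detrend_window", "temporal_lowpass_window"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0 and v % 2 == 1):
                raise ValidationError(f"{name} must be an odd positive integer, got {v}")
        if not self.spatial_detrend_window > self.temporal_lowpass_window:
            raise ValidationError("spatial_detrend_window must exceed temporal_lowpass_window")

    def to_dict(self) -> dict:
        return asdict(self)


def _oriented(values: np.ndarray, calibration: CalibrationConfig) -> np.ndarray:
    """Flip the space axis if the oviduct is on the image's right edge."""
    if calibration.orientation == "right":
        return values[::-1].copy()
    return values


def column_area(
    boundaries: HornBoundaries, calibration: CalibrationConfig | None = None
) -> SpatioTemporalMap:
    """Area map: per-column boundary distance in pixels.

    ``values[c, t] = lower[t, c] - upper[t, c]`` (each pixel has unit
    width, so the distance doubles as a cross-section proxy). Invalid
    and zero-width (clamped) columns are masked.
    """
    calibration = calibration or CalibrationConfig()
    area = (boundaries.lower - boundaries.upper).T.astype(float)
    bad = ~boundaries.valid.T | ~(area > 0)
    area[bad] = np.nan
    return SpatioTemporalMap(
        values=_oriented(area, calibration), quantity="area_px", calibration=calibration
    )


def column_mean_intensity(
    stack: FrameStack,
    boundaries: HornBoundaries,
    calibration: CalibrationConfig | None = None,
) -> SpatioTemporalMap:
    """Intensity map: per-column mean of the *raw* pixels between boundaries.

    Rows ``ceil(upper) .. floor(lower)`` inclusive enter the mean; the
    smoothed stack used for boundary detection never does. Cells whose
    row run is empty are masked.
    """
    calibration = calibration or CalibrationConfig()
    if (stack.n_frames, stack.width) != boundaries.upper.shape:
        raise ValidationError(
            f"stack ({stack.n_frames} frames x {stack.width} cols) does not match "
            f"boundaries {boundaries.upper.shape}"
        )
    nt, h, nc = stack.frames.shape
    out = np.full((nc, nt), np.nan)

    i0 = np.ceil(boundaries.upper)
    i1 = np.floor(boundaries.lower)
    ok = boundaries.valid & np.isfinite(i0) & np.isfinite(i1) & (i1 >= i0)
    i0c = np.clip(np.nan_to_num(i0), 0, h - 1).astype(int)
    i1c = np.clip(np.nan_to_num(i1), 0, h - 1).astype(int)

    for t in range(nt):
        frame = stack.frames[t].astype(np.float64)
        cs = np.vstack([np.zeros((1, nc)), np.cumsum(frame, axis=0)])
        cols = np.flatnonzero(ok[t])
        if cols.size == 0:
            continue
        lo, hi = i0c[t, cols], i1c[t, cols]
        sums = cs[hi + 1, cols] - cs[lo, cols]
        out[cols, t] = sums / (hi - lo + 1)

    return SpatioTemporalMap(
        values=_oriented(out, calibration),
        quantity="mean_intensity",
        calibration=calibration,
    )


def _nan_fill(values: np.ndarray) -> np.ndarray:
    """Fill NaNs by nearest-valid along the space axis (per frame)."""
    out = values.copy()
    for t in range(out.shape[1]):
        col = out[:, t]
        bad = ~np.isfinite(col)
        if bad.all():
            out[:, t] = 0.0
        elif bad.any():
            idx = np.arange(col.size)
            out[bad, t] = np.interp(idx[bad], idx[~bad], col[~bad])
    return out


def _moving_average(values: np.ndarray, window: int, axis: int) -> np.ndarray:
    kernel = np.full(window, 1.0 / window)
    return convolve1d(values, kernel, axis=axis, mode="nearest")


def enhance(m: SpatioTemporalMap, params: EnhanceParams | None = None) -> SpatioTemporalMap:
    """Enhance a raw map into its change-detected, filtered form.

    Pipeline: (1) Sobel gradient magnitude at ``change_kernel`` on the
    space x time matrix; (2) subtract a centred moving average of width
    ``spatial_detrend_window`` along space; (3) centred moving average
    of width ``temporal_lowpass_window`` along time. Masked cells are
    filled by nearest-valid interpolation for the convolutions and
    re-masked afterwards.
    """
    params = params or EnhanceParams()
    if min(m.values.shape) < params.change_kernel:
        raise FrameSizeError(
            f"map {m.values.shape} smaller than change kernel {params.change_kernel}"
        )
    if m.quantity.startswith("enhanced"):
        raise ValidationError("map is already enhanced")

    filled = _nan_fill(m.values)
    smooth, deriv = sobel_kernels(params.change_kernel)
    gs = convolve1d(convolve1d(filled, deriv, axis=0, mode="nearest"),
                    smooth, axis=1, mode="nearest")
    gt = convolve1d(convolve1d(filled, deriv, axis=1, mode="nearest"),
                    smooth, axis=0, mode="nearest")
    grad = np.hypot(gs, gt)

    detrended = grad - _moving_average(grad, params.spatial_detrend_window, axis=0)
    lowpassed = _moving_average(detrended, params.temporal_lowpass_window, axis=1)

    lowpassed[m.mask] = np.nan
    quantity = "enhanced_area" if m.quantity == "area_px" else "enhanced_intensity"
    return SpatioTemporalMap(values=lowpassed, quantity=quantity, calibration=m.calibration)


def render_map(m: SpatioTemporalMap, path, cmap: str = "viridis") -> None:
    """Render a map as a Hovmöller PNG: space (mm) vs time (s)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cal = m.calibration
    extent = (0.0, m.n_columns / cal.px_per_mm, m.n_frames / cal.fps, 0.0)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(m.values.T, aspect="auto", cmap=cmap, extent=extent,
                   interpolation="nearest")
    ax.set_xlabel("distance along horn, oviduct → cervix (mm)")
    ax.set_ylabel("time (s)")
    fig.colorbar(im, ax=ax, label=m.quantity)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
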