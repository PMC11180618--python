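"""Video and table input/output.

Reading
-------
:func:`load_video` accepts

* a multi-page TIFF stack (lossless; the recommended interchange format),
* a directory of numbered PNG/TIFF frames (lossless image sequence),
* any container imageio can decode with its installed plugins
  (AVI/Xvid and MP4 work when an ffmpeg-capable plugin is present).

Colour input is converted to luminance with a warning, because the
contraction signal lives in the intensity of a single fluorescence
channel and channel mixing would corrupt it.

Tables
------
Every tabular artifact (boundaries, spatiotemporal maps, wave
annotations, wave metrics) is written as a UTF-8 comma-separated file
with a header row plus a JSON sidecar (same stem, ``.json``) carrying
calibration, parameters and provenance, so that any output can be traced
back to the command that produced it. ``read_*(write_*(x))`` reproduces
``x`` to full numeric precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationConfig
from .errors import (
    BoundsError,
    DecodeError,
    TableFormatError,
    ValidationError,
    VideoFormatError,
)

_LUMA = np.array([0.299, 0.587, 0.114])

_SEQUENCE_EXTS = (".png", ".tif", ".tiff")


@dataclass
class FrameStack:
    """An ordered stack of grayscale frames.

    Attributes
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with intensities in
        ``[0, 255]``. Row 0 is the image top, column 0 the image left;
        all pixel coordinates in the package are 0-based.
    frame_interval
        Seconds between successive frames (> 0).
    """

    frames: np.ndarray
    frame_interval: float = 0.2

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be (time, row, column), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValidationError(
                f"a frame stack needs at least 2 frames, got {self.frames.shape[0]}"
            )
        if not self.frame_interval > 0:
            raise ValidationError(f"frame_interval must be > 0, got {self.frame_interval}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0 or hi > 255:
            raise ValidationError(
                f"intensities must lie in [0, 255], got range [{lo}, {hi}]"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_interval


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a (T, H, W[, C]) array to single-channel luminance."""
    if arr.ndim == 3:
        return arr
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        warnings.warn(
            "colour video converted to luminance; the contraction signal should "
            "come from a single fluorescence channel",
            stacklevel=3,
        )
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ _LUMA
    raise VideoFormatError(f"cannot interpret frame array of shape {arr.shape}")


def _load_image_sequence(directory: Path) -> np.ndarray:
    import imageio.v3 as iio

    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _SEQUENCE_EXTS
    )
    if not paths:
        raise DecodeError(f"no PNG/TIFF frames found in directory {directory}")
    frames = [np.asarray(iio.imread(p)) for p in paths]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise VideoFormatError(f"inconsistent frame shapes in {directory}: {shapes}")
    return np.stack(frames)


def load_video(path, expected_interval: float | None = None) -> FrameStack:
    """Read a video into a :class:`FrameStack`.

    Parameters
    ----------
    path
        TIFF stack, frame-sequence directory, or any imageio-decodable
        container.
    expected_interval
        Seconds per frame. Overrides container metadata when given;
        required in practice for formats that carry no frame rate
        (TIFF stacks default to 0.2 s/frame with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"video path does not exist: {path}")

    interval = expected_interval
    if path.is_dir():
        arr = _load_image_sequence(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise DecodeError(f"could not decode TIFF stack {path}: {exc}") from exc
    else:
        try:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path, plugin=None))
            if interval is None:
                meta = iio.immeta(path)
                fps = meta.get("fps")
                if fps:
                    interval = 1.0 / float(fps)
        except DecodeError:
            raise
        except Exception as exc:
            raise DecodeError(
                f"could not decode {path}; AVI/MP4 support requires an "
                f"ffmpeg-capable imageio plugin ({exc})"
            ) from exc

    if arr.ndim == 2:
        raise ValidationError(
            f"{path} holds a single frame; a frame stack needs at least 2"
        )
    gray = _to_gray(arr)
    if interval is None:
        warnings.warn(
            "no frame interval in container metadata; defaulting to 0.2 s/frame",
            stacklevel=2,
        )
        interval = 0.2
    return FrameStack(frames=gray, frame_interval=interval)


def save_video(stack: FrameStack, path) -> Path:
    """Write a stack losslessly (TIFF file or PNG-sequence directory)."""
    path = Path(path)
    data = np.clip(np.round(stack.frames), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        ndig = len(str(stack.n_frames - 1))
        for t in range(stack.n_frames):
            iio.imwrite(path / f"frame_{t:0{ndig}d}.png", data[t])
    return path


def crop(stack: FrameStack, rect: tuple[int, int, int, int]) -> FrameStack:
    """Restrict a stack to ``rect = (row0, row1, col0, col1)``, half-open.

    Used to isolate one uterine horn per video. The cropped height must
    still admit two distinct boundaries (>= 2 rows).
    """
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= stack.height and 0 <= c0 < c1 <= stack.width):
        raise BoundsError(
            f"rect {rect} outside frame bounds {stack.height}x{stack.width} or empty"
        )
    if r1 - r0 < 2:
        raise BoundsError("cropped height < 2 rows cannot contain two boundaries")
    return FrameStack(
        frames=stack.frames[:, r0:r1, c0:c1].copy(),
        frame_interval=stack.frame_interval,
    )


# ---------------------------------------------------------------------------
# CSV + JSON-sidecar table IO
# ---------------------------------------------------------------------------

def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def _write_sidecar(path, kind: str, calibration: CalibrationConfig | None = None,
                   params: dict | None = None, source: str | None = None,
                   extra: dict | None = None) -> None:
    meta: dict = {"kind": kind, "writer": "myowave"}
    if calibration is not None:
        meta["calibration"] = calibration.to_dict()
    if params:
        meta["params"] = params
    if source:
        meta["source"] = source
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_sidecar(path) -> dict:
    p = sidecar_path(path)
    if not p.exists():
        return {}
    return json.loads(p.read_text())


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{what} table is missing required column(s): {', '.join(missing)}"
        )


def write_boundaries(b, path, calibration=None, params: dict | None = None,
                     source: str | None = None) -> Path:
    """Write per-frame per-column boundaries as long-format CSV."""
    path = Path(path)
    t_idx, c_idx = np.nonzero(np.ones_like(b.valid, dtype=bool))
    df = pd.DataFrame(
        {
            "frame": t_idx,
            "column": c_idx,
            "upper": b.upper.ravel(),
            "lower": b.lower.ravel(),
            "valid": b.valid.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)
    _write_sidecar(path, "horn_boundaries", calibration, params, source,
                   extra={"n_frames": int(b.upper.shape[0]),
                          "n_columns": int(b.upper.shape[1])})
    return path


def read_boundaries(path):
    from .boundary import HornBoundaries

    df = pd.read_csv(path)
    _require_columns(df, ["frame", "column", "upper", "lower", "valid"], "boundaries")
    nt = int(df["frame"].max()) + 1
    nc = int(df["column"].max()) + 1
    upper = np.full((nt, nc), np.nan)
    lower = np.full((nt, nc), np.nan)
    valid = np.zeros((nt, nc), dtype=bool)
    ti = df["frame"].to_numpy()
    ci = df["column"].to_numpy()
    upper[ti, ci] = df["upper"].to_numpy()
    lower[ti, ci] = df["lower"].to_numpy()
    valid[ti, ci] = df["valid"].to_numpy().astype(bool)
    return HornBoundaries(upper=upper, lower=lower, valid=valid)


def write_map(m, path, source: str | None = None, params: dict | None = None) -> Path:
    """Write a spatiotemporal map as a (space x time) CSV matrix."""
    path = Path(path)
    df = pd.DataFrame(m.values)
    df.index.name = "column"
    df.columns = [str(t) for t in range(m.values.shape[1])]
    df.to_csv(path)
    _write_sidecar(path, "spatiotemporal_map", m.calibration, params, source,
                   extra={"quantity": m.quantity})
    return path


def read_map(path):
    from .stmaps import SpatioTemporalMap

    df = pd.read_csv(path, index_col=0)
    meta = read_sidecar(path)
    cal = CalibrationConfig.from_dict(meta.get("calibration", {}))
    return SpatioTemporalMap(
        values=df.to_numpy(dtype=float),
        quantity=meta.get("quantity", "mean_intensity"),
        calibration=cal,
    )


_ANNOTATION_COLS = ["map_id", "ridge_c0", "ridge_t0", "ridge_c1", "ridge_t1",
                    "band_c0", "band_c1", "next_ridge_t"]


def write_annotations(annotations: Iterable, path, source: str | None = None) -> Path:
    path = Path(path)
    rows = []
    for a in annotations:
        rows.append(
            {
                "map_id": a.map_id,
                "ridge_c0": a.ridge[0][0],
                "ridge_t0": a.ridge[0][1],
                "ridge_c1": a.ridge[1][0],
                "ridge_t1": a.ridge[1][1],
                "band_c0": a.band_extent[0],
                "band_c1": a.band_extent[1],
                "next_ridge_t": a.next_ridge_frame,
            }
        )
    pd.DataFrame(rows, columns=_ANNOTATION_COLS).to_csv(path, index=False)
    _write_sidecar(path, "wave_annotations", source=source)
    return path


def read_annotations(path) -> list:
    from .waves import WaveAnnotation

    df = pd.read_csv(path)
    _require_columns(df, _ANNOTATION_COLS, "annotation")
    if df.empty:
        raise TableFormatError(f"annotation table {path} contains no waves")
    out = []
    for row in df.itertuples(index=False):
        nrf = row.next_ridge_t
        out.append(
            WaveAnnotation(
                ridge=((float(row.ridge_c0), float(row.ridge_t0)),
                       (float(row.ridge_c1), float(row.ridge_t1))),
                band_extent=(float(row.band_c0), float(row.band_c1)),
                next_ridge_frame=None if pd.isna(nrf) else float(nrf),
                map_id=str(row.map_id),
            )
        )
    return out


_METRIC_COLS = ["amplitude_um", "period_s", "frequency_hz", "velocity_um_s",
                "wavelength_um", "direction", "segment"]


def write_metrics(metrics: Iterable, path, calibration=None,
                  source: str | None = None, extra: dict | None = None) -> Path:
    path = Path(path)
    rows = [m.to_dict() for m in metrics]
    pd.DataFrame(rows, columns=_METRIC_COLS).to_csv(path, index=False)
    _write_sidecar(path, "wave_metrics", calibration, source=source, extra=extra)
    return path


def read_metrics(path) -> list:
    from .waves import WaveMetrics

    df = pd.read_csv(path)
    _require_columns(df, _METRIC_COLS, "metrics")

    def _opt(v):
        return None if pd.isna(v) else float(v)

    out = []
    for row in df.itertuples(index=False):
        out.append(
            WaveMetrics(
                amplitude_um=float(row.amplitude_um),
                velocity_um_s=float(row.velocity_um_s),
                direction=str(row.direction),
                period_s=_opt(row.period_s),
                frequency_hz=_opt(row.frequency_hz),
                wavelength_um=_opt(row.wavelength_um),
                segment=None if pd.isna(row.segment) else str(row.segment),
            )
        )
    return out
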