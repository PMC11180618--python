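"""Synthetic contracting-tube videos with known wave parameters.

The simulator renders a horizontally pinned bright tube on a dark
background, traversed by travelling constriction waves, and returns the
exact ground truth (crest trajectories, speed, spacing, band width)
alongside the frames — so every upstream module can be validated
without any real recording.

Geometry and intensity model
----------------------------
The tube is centred vertically with relaxed half-diameter ``r0``. A
periodic raised-cosine bump train ``w`` (unit peak, compact support
``band_width``, spacing ``wave_spacing``) travels at the configured
speed. In *circular* mode the local half-diameter is
``r = r0 * (1 - a * w)`` and, because compressed tissue concentrates
the fluorophore, the interior intensity rises as ``I0 * (r0 / r)**gamma``
— with ``gamma = 1`` the per-column product of mean intensity and
diameter is conserved over time. In *longitudinal* mode the diameter
stays fixed and only a density wave ``I0 * (1 + a * w)**gamma`` passes:
the discriminating case in which intensity maps show ridges that area
maps cannot.

Realism knobs: thin, dim, low-gradient horn ends (``taper_fraction``),
per-pixel Gaussian noise, static bright stain-like blobs outside the
tube, and 8-bit quantisation of the rendered frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .calibration import CalibrationConfig
from .errors import GeometryError, ValidationError
from .video_io import FrameStack
from .waves import WaveAnnotation

_TAPER_MIN = 0.25  # relative half-diameter / brightness at the horn's tips


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of a synthetic contraction recording.

    Defaults emulate the reference acquisition: a 5-minute video at
    5 frames/s, 110.85 px/mm, and a wave train at the scale reported
    for the most contractile (diestrus) stage — 12.8 um/s speed,
    800 um crest spacing, 190 um band width.
    """

    width: int = 1200
    height: int = 160
    duration_s: float = 300.0
    fps: float = 5.0
    px_per_mm: float = 110.85
    r0: float = 40.0
    wave_speed_um_s: float = 12.8
    wave_spacing_um: float = 800.0
    band_width_um: float = 190.0
    constriction_fraction: float = 0.3
    direction: str = "toward_cervix"
    mode: str = "circular"
    gamma: float = 1.0
    noise_sd: float = 0.0
    artifact_count: int = 0
    taper_fraction: float = 0.08
    base_intensity: float = 120.0
    edge_softness_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("width", "height", "duration_s", "fps", "px_per_mm", "r0",
                     "wave_speed_um_s", "wave_spacing_um", "band_width_um",
                     "base_intensity", "edge_softness_px"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.constriction_fraction < 1:
            raise ValidationError("constriction_fraction must lie in [0, 1)")
        if not self.band_width_um < self.wave_spacing_um:
            raise ValidationError("band_width_um must be smaller than wave_spacing_um")
        if self.direction not in ("toward_cervix", "toward_oviduct"):
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.mode not in ("circular", "longitudinal"):
            raise ValidationError(f"bad mode {self.mode!r}")
        if not 0 <= self.taper_fraction < 0.5:
            raise ValidationError("taper_fraction must lie in [0, 0.5)")
        if self.noise_sd < 0 or self.artifact_count < 0:
            raise ValidationError("noise_sd and artifact_count must be >= 0")
        if 2 * self.r0 >= 0.8 * self.height:
            raise GeometryError(
                f"tube diameter {2 * self.r0} px does not fit height "
                f"{self.height} px (needs < 80%)"
            )

    # -- derived scales ----------------------------------------------------
    @property
    def um_per_px(self) -> float:
        return 1000.0 / self.px_per_mm

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def speed_px_per_frame(self) -> float:
        """Signed crest speed in pixels/frame (+ toward the cervix)."""
        s = 1.0 if self.direction == "toward_cervix" else -1.0
        return s * self.wave_speed_um_s / self.um_per_px / self.fps

    @property
    def spacing_px(self) -> float:
        return self.wave_spacing_um / self.um_per_px

    @property
    def band_width_px(self) -> float:
        return self.band_width_um / self.um_per_px

    @property
    def calibration(self) -> CalibrationConfig:
        return CalibrationConfig(fps=self.fps, px_per_mm=self.px_per_mm,
                                 orientation="left")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Exact wave state of a simulation.

    Knows the crest trajectories ``x_k(t) = x0 + k * spacing + v * t``
    and can produce true boundaries for any frame and true annotations
    in :class:`~myowave.waves.WaveAnnotation` form. The derived true
    frequency equals speed / spacing by construction.
    """

    params: SimulationParams
    crest_offset_px: float  # x0: column of crest 0 at frame 0

    @property
    def velocity_um_s(self) -> float:
        return self.params.wave_speed_um_s

    @property
    def frequency_hz(self) -> float:
        return self.params.wave_speed_um_s / self.params.wave_spacing_um

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def period_frames(self) -> float:
        return self.params.spacing_px / abs(self.params.speed_px_per_frame)

    # -- continuous wave fields --------------------------------------------
    def bump(self, x: np.ndarray, t: float) -> np.ndarray:
        """Unit bump-train value at columns ``x``, frame ``t``."""
        p = self.params
        phase = np.mod(x - self.crest_offset_px - p.speed_px_per_frame * t,
                       p.spacing_px)
        d = np.where(phase > p.spacing_px / 2, phase - p.spacing_px, phase)
        w = np.cos(np.pi * d / p.band_width_px) ** 2
        return np.where(np.abs(d) <= p.band_width_px / 2, w, 0.0)

    def taper(self, x: np.ndarray) -> np.ndarray:
        """End taper factor in [_TAPER_MIN, 1] along the horn axis."""
        p = self.params
        ramp_len = p.taper_fraction * p.width
        if ramp_len <= 0:
            return np.ones_like(np.asarray(x, dtype=float))
        d_edge = np.minimum(x, p.width - 1 - np.asarray(x, dtype=float))
        u = np.clip(d_edge / ramp_len, 0.0, 1.0)
        return _TAPER_MIN + (1 - _TAPER_MIN) * 0.5 * (1 - np.cos(np.pi * u))

    def half_diameter(self, x: np.ndarray, t: float) -> np.ndarray:
        """True tube half-diameter (px) including end taper."""
        p = self.params
        if p.mode == "circular":
            r = p.r0 * (1 - p.constriction_fraction * self.bump(x, t))
        else:
            r = np.full_like(np.asarray(x, dtype=float), p.r0)
        return r * self.taper(x)

    def interior_intensity(self, x: np.ndarray, t: float) -> np.ndarray:
        """True interior intensity (0-255 scale) including end dimming."""
        p = self.params
        w = self.bump(x, t)
        if p.mode == "circular":
            rel = (1 - p.constriction_fraction * w) ** (-p.gamma)
        else:
            rel = (1 + p.constriction_fraction * w) ** p.gamma
        return p.base_intensity * rel * self.taper(x)

    def boundary_truth(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """True (upper, lower) boundary rows for every column at frame t."""
        x = np.arange(self.params.width)
        r = self.half_diameter(x, t)
        yc = (self.params.height - 1) / 2
        return yc - r, yc + r

    def crest_columns(self, t: float) -> np.ndarray:
        """Columns of all crests inside the frame at frame ``t``."""
        p = self.params
        base = self.crest_offset_px + p.speed_px_per_frame * t
        k_lo = math.ceil((0 - base) / p.spacing_px)
        k_hi = math.floor((p.width - 1 - base) / p.spacing_px)
        return base + np.arange(k_lo, k_hi + 1) * p.spacing_px


def ground_truth(params: SimulationParams) -> GroundTruth:
    """Ground truth for a parameter set (no frames rendered)."""
    # put a crest at mid-width at frame 0 so short recordings see a wave
    return GroundTruth(params=params, crest_offset_px=params.width / 2.0)


def _stain_blobs(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Static bright blobs outside the tube (petri-dish stains)."""
    h, w = params.height, params.width
    img = np.zeros((h, w))
    yc = (h - 1) / 2
    ys, xs = np.mgrid[0:h, 0:w]
    for _ in range(params.artifact_count):
        cx = rng.uniform(0.05 * w, 0.95 * w)
        side = rng.choice([-1.0, 1.0])
        margin_lo = params.r0 + 6.0
        margin_hi = max(margin_lo + 2.0, yc - 3.0)
        cy = yc + side * rng.uniform(margin_lo, margin_hi)
        sigma = rng.uniform(2.0, 4.0)
        peak = rng.uniform(150.0, 230.0)
        img += peak * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    return img


def simulate_video(params: SimulationParams | None = None) -> tuple[FrameStack, GroundTruth]:
    """Render a synthetic contraction video plus its ground truth.

    All randomness (noise, blob placement) derives from ``params.seed``;
    identical parameters give bit-identical stacks. Frames are rendered
    in float, quantised to 8 bits after noise.
    """
    params = params or SimulationParams()
    gt = ground_truth(params)
    rng = np.random.default_rng(params.seed)
    h, w, nt = params.height, params.width, params.n_frames
    if nt < 2:
        raise ValidationError("duration_s * fps must give at least 2 frames")

    yc = (h - 1) / 2
    y = np.arange(h)[:, None]  # (H, 1)
    x = np.arange(w)[None, :]  # (1, W)
    blobs = _stain_blobs(params, rng) if params.artifact_count else None

    frames = np.empty((nt, h, w), dtype=np.uint8)
    for t in range(nt):
        r = gt.half_diameter(x[0], t)[None, :]
        intensity = gt.interior_intensity(x[0], t)[None, :]
        coverage = np.clip((r - np.abs(y - yc)) / params.edge_softness_px + 0.5,
                           0.0, 1.0)
        frame = intensity * coverage
        if blobs is not None:
            frame = frame + blobs
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        frames[t] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    stack = FrameStack(frames=frames, frame_interval=1.0 / params.fps)
    return stack, gt


def _feasible_crests(gt: GroundTruth, span: float, margin: float) -> dict[int, tuple[float, float]]:
    """Crest indices whose full ridge fits the frame, with t0 windows."""
    p = gt.params
    v = p.speed_px_per_frame
    t_max = p.n_frames - 1 - span
    out: dict[int, tuple[float, float]] = {}
    lo_col, hi_col = margin, p.width - 1 - margin
    # x_k(t) = x0 + k*spacing + v*t must stay in [lo_col, hi_col] on [t0, t0+span]
    k_range = int(np.ceil((p.width + abs(v) * p.n_frames) / p.spacing_px)) + 2
    for k in range(-k_range, k_range + 1):
        xk0 = gt.crest_offset_px + k * p.spacing_px
        if v > 0:
            t_lo = (lo_col - xk0) / v
            t_hi = (hi_col - xk0) / v - span
        else:
            t_lo = (hi_col - xk0) / v
            t_hi = (lo_col - xk0) / v - span
        t_lo, t_hi = max(t_lo, 0.0), min(t_hi, t_max)
        if t_hi >= t_lo:
            out[k] = (t_lo, t_hi)
    return out


def truth_annotations(
    gt: GroundTruth,
    n_waves: int,
    seed: int | None = None,
    jitter_px: float = 0.0,
    span_frames: float | None = None,
    target_columns: list[float] | None = None,
) -> list[WaveAnnotation]:
    """Exact wave annotations sampled from the ground truth.

    Each annotation traces one crest over ``span_frames`` frames (by
    default ~80% of one wave period, capped at half the recording),
    marks the true band extent, and records the true next-crest arrival
    frame — directly usable by :func:`myowave.waves.compute_metrics`.

    ``jitter_px`` adds Gaussian scatter to the marked columns, emulating
    manual ridge placement; zero (the default) keeps annotations exact.
    ``target_columns`` requests ridge midpoints near given columns (one
    annotation per target), e.g. to cover all three horn segments.
    """
    p = gt.params
    rng = np.random.default_rng(seed)
    v = p.speed_px_per_frame
    if span_frames is None:
        span_frames = min(0.8 * gt.period_frames, 0.5 * (p.n_frames - 1))
    margin = p.band_width_px / 2 + 1
    feasible = _feasible_crests(gt, span_frames, margin)
    if target_columns is None and n_waves > len(feasible):
        raise ValidationError(
            f"requested {n_waves} waves but only {len(feasible)} crests fit "
            "fully inside the recording window"
        )

    picks: list[tuple[int, float]] = []  # (crest index, t0)
    if target_columns is not None:
        for c in target_columns:
            # place the ridge's mid-time near the recording's middle
            best = None
            for k, (t_lo, t_hi) in feasible.items():
                t_mid_lo, t_mid_hi = t_lo + span_frames / 2, t_hi + span_frames / 2
                t_star = np.clip((c - gt.crest_offset_px - k * p.spacing_px) / v
                                 - span_frames / 2, t_lo, t_hi)
                x_mid = gt.crest_offset_px + k * p.spacing_px + v * (t_star + span_frames / 2)
                err = abs(x_mid - c)
                if best is None or err < best[0]:
                    best = (err, k, float(t_star))
            if best is None:
                raise ValidationError("no crest fits the recording window")
            picks.append((best[1], best[2]))
    else:
        ks = rng.choice(sorted(feasible), size=n_waves, replace=False)
        for k in ks:
            t_lo, t_hi = feasible[int(k)]
            picks.append((int(k), float(rng.uniform(t_lo, t_hi))))

    out: list[WaveAnnotation] = []
    for k, t0 in picks:
        t1 = t0 + span_frames
        c0 = gt.crest_offset_px + k * p.spacing_px + v * t0
        c1 = gt.crest_offset_px + k * p.spacing_px + v * t1
        band_lo = c0 - p.band_width_px / 2
        band_hi = c0 + p.band_width_px / 2
        if jitter_px > 0:
            c0 += rng.normal(0, jitter_px)
            c1 += rng.normal(0, jitter_px)
            shift = rng.normal(0, jitter_px)
            stretch = rng.normal(0, jitter_px)
            band_lo += shift - abs(stretch) / 2
            band_hi += shift + abs(stretch) / 2
        out.append(
            WaveAnnotation(
                ridge=((c0, t0), (c1, t1)),
                band_extent=(band_lo, band_hi),
                next_ridge_frame=t0 + gt.period_frames,
                map_id="simulated",
            )
        )
    return out
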