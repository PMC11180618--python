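"""Embryo-position arithmetic along the uterine horn.

Inputs are 3D coordinates (from surface renderings of confocal stacks)
of the oviductal–uterine junction (OUJ) and of each embryo centre, plus
the measured horn length. Distances use the orthogonal projection onto
the XY plane, are normalised by horn length, and position each embryo
in the oviductal / middle / cervical third of the horn. Horns carrying
fewer than three embryos are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import HornExclusionError, ValidationError

MIN_EMBRYOS = 3


@dataclass
class HornPointSet:
    """OUJ coordinate, embryo centres, and horn length (shared units)."""

    ouj: tuple[float, float, float]
    embryos: list[tuple[float, float, float]] = field(default_factory=list)
    horn_length: float = 1.0

    def __post_init__(self) -> None:
        if not self.horn_length > 0:
            raise ValidationError(f"horn_length must be > 0, got {self.horn_length}")
        pts = np.asarray([self.ouj, *self.embryos], dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValidationError("coordinates must be finite")


def _require_enough(points: HornPointSet) -> None:
    if len(points.embryos) < MIN_EMBRYOS:
        raise HornExclusionError(
            f"horn excluded: {len(points.embryos)} embryo(s) < required {MIN_EMBRYOS}"
        )


def _xy(p) -> np.ndarray:
    return np.asarray(p, dtype=float)[:2]


def normalized_positions(points: HornPointSet) -> list[float]:
    """Normalized oviduct–embryo (OE) distances, sorted ascending.

    OE = Euclidean distance between the XY projections of the OUJ and
    the embryo, divided by horn length. Values can slightly exceed 1
    when the projection straightens a curved horn path.
    """
    _require_enough(points)
    ouj = _xy(points.ouj)
    oe = [float(np.linalg.norm(_xy(e) - ouj)) / points.horn_length
          for e in points.embryos]
    return sorted(oe)


def ee_distances(points: HornPointSet) -> list[float]:
    """Normalized distances between adjacent embryos (EE).

    Adjacency follows ascending OE order; distances are XY-projected
    and normalised by horn length. Because pairs are measured directly,
    the EE sum can exceed the horn span when embryos sit off-axis.
    """
    _require_enough(points)
    ouj = _xy(points.ouj)
    embryos = sorted(points.embryos,
                     key=lambda e: float(np.linalg.norm(_xy(e) - ouj)))
    out = []
    for p, q in zip(embryos[:-1], embryos[1:]):
        out.append(float(np.linalg.norm(_xy(q) - _xy(p))) / points.horn_length)
    return out


def segment_percentages(norm_positions: list[float]) -> dict[str, float]:
    """Percentage of embryos in each third of the horn.

    Thirds of normalised position: ``[0, 1/3)``, ``[1/3, 2/3)``,
    ``[2/3, inf)``. Embryos at (or slightly before) the junction count
    in the oviductal third; positions slightly beyond 1 (projection
    shorter than the measured path) count in the cervical third.
    """
    pos = np.asarray(norm_positions, dtype=float)
    if pos.size == 0:
        raise ValidationError("need at least one position")
    pos = np.maximum(pos, 0.0)  # junction-adjacent embryos -> oviductal third
    counts = {
        "oviductal": int(np.sum(pos < 1 / 3)),
        "middle": int(np.sum((pos >= 1 / 3) & (pos < 2 / 3))),
        "cervical": int(np.sum(pos >= 2 / 3)),
    }
    return {k: 100.0 * v / pos.size for k, v in counts.items()}
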