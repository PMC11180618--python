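"""Regional analysis: oviductal / middle / cervical thirds of the horn.

Contractility differs along the horn (e.g. the middle is most active
during clustered embryo movement), so waves are assigned to thirds of
the spatial axis and a fixed number per third is sampled for per-horn
analysis — the protocol samples three waves from each of the three
segments, nine waves per horn.
"""

from __future__ import annotations

import numpy as np

from .errors import BoundsError, UndersizedSegmentError, ValidationError
from .waves import WaveAnnotation

SEGMENT_LABELS = ("oviductal", "middle", "cervical")


def segment_bounds(n_columns: int) -> tuple[int, int]:
    """Column boundaries of the three thirds: ``floor(n/3), floor(2n/3)``.

    The thirds ``[0, b1)``, ``[b1, b2)``, ``[b2, n)`` partition the
    spatial axis exactly.
    """
    if n_columns < 3:
        raise ValidationError(f"need at least 3 columns to form thirds, got {n_columns}")
    return n_columns // 3, (2 * n_columns) // 3


def assign_segment(ann: WaveAnnotation, n_columns: int) -> str:
    """Segment of a wave: the third holding its ridge midpoint column.

    Intervals are half-open, so a midpoint exactly at ``n/3`` falls in
    the middle segment.
    """
    b1, b2 = segment_bounds(n_columns)
    mid = ann.midpoint_column
    if not (0 <= mid < n_columns):
        raise BoundsError(
            f"ridge midpoint column {mid} outside map [0, {n_columns})"
        )
    if mid < b1:
        return "oviductal"
    if mid < b2:
        return "middle"
    return "cervical"


def sample_waves(
    annotations: list[WaveAnnotation],
    n_columns: int,
    per_segment: int = 3,
    seed: int | None = None,
) -> list[WaveAnnotation]:
    """Sample ``per_segment`` waves uniformly from each third, seeded.

    Raises :class:`UndersizedSegmentError` naming any segment holding
    fewer than ``per_segment`` annotated waves. With the default of 3
    per segment this yields the protocol's nine waves per horn.
    """
    rng = np.random.default_rng(seed)
    by_segment: dict[str, list[WaveAnnotation]] = {s: [] for s in SEGMENT_LABELS}
    for ann in annotations:
        by_segment[assign_segment(ann, n_columns)].append(ann)

    sampled: list[WaveAnnotation] = []
    for label in SEGMENT_LABELS:
        pool = by_segment[label]
        if len(pool) < per_segment:
            raise UndersizedSegmentError(
                f"segment '{label}' has only {len(pool)} annotated wave(s), "
                f"need {per_segment}"
            )
        idx = rng.choice(len(pool), size=per_segment, replace=False)
        sampled.extend(pool[i] for i in sorted(idx))
    return sampled
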