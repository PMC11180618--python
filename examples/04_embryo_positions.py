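"""Embryo positions along a uterine horn from 3D point coordinates.

The oviductal-uterine junction, five embryo centres and the horn
length come from 3D surface renderings; everything here is the
downstream arithmetic: XY-projected distances, normalisation by horn
length, and assignment to oviductal/middle/cervical thirds.
"""

import myowave as mw

points = mw.HornPointSet(
    ouj=(0.0, 0.0, 12.0),
    embryos=[(1.1, 0.4, 11.0), (2.3, 0.9, 10.5), (3.0, 1.4, 10.2),
             (4.4, 1.6, 9.8), (5.2, 2.2, 9.5)],
    horn_length=7.0,
)

oe = mw.normalized_positions(points)
ee = mw.ee_distances(points)
pct = mw.segment_percentages(oe)

print("normalized oviduct-embryo distances:",
      " ".join(f"{d:.3f}" for d in oe))
print("normalized adjacent-embryo spacing :",
      " ".join(f"{d:.3f}" for d in ee))
print("embryos per third of the horn      : "
      f"oviductal {pct['oviductal']:.0f}%, middle {pct['middle']:.0f}%, "
      f"cervical {pct['cervical']:.0f}%")
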