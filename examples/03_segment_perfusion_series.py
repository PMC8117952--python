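"""Segment the myocardium from the dynamic perfusion series, slice by
slice (base -> mid -> apex, ventricles propagated by temporal
correlation), and score each annulus against the phantom truth.
"""
import numpy as np

from mbfseg.core import Condition, SliceLocation
from mbfseg.landmarks import detect_ventricles
from mbfseg.perfseg import propagate_slice, segment_perfusion_slice
from mbfseg.phantom import PhantomConfig, generate_phantom

SLICES = (SliceLocation.BASE, SliceLocation.MID, SliceLocation.APEX)


def dice(a, b):
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())


study = generate_phantom(PhantomConfig(rng_seed=4))
prev_v = detect_ventricles(study.series[(SliceLocation.BASE,
                                         Condition.REST)])
prev_s = study.series[(SliceLocation.BASE, Condition.REST)]
for loc in SLICES:
    s = study.series[(loc, Condition.REST)]
    v = prev_v if loc is SliceLocation.BASE else propagate_slice(
        prev_v, prev_s, s)
    seg = segment_perfusion_slice(s, v)
    d = dice(seg.myo_mask, study.truth[loc].myo_mask)
    rv = "RV present" if v.rv_mask is not None else "RV absent"
    print(f"{loc.value:>5}: myocardial Dice vs truth {d:.3f} "
          f"({seg.myo_mask.sum()} px, {rv})")
# Dice around 0.9 under realistic noise; the apex has no visible RV, and
# processing continues without it, exactly as on clinical apical slices.
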