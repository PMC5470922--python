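"""Ghost suppression: color-only ViBe vs depth-extended DEVB.

Builds the canonical ghost scene — an object present in frame 1 that
departs — and measures the false-positive fraction inside the departed
object's footprint for both segmenters.  ViBe keeps detecting a blob
that no longer exists (the ghost); DEVB's depth model recognizes that
the surface there moved away and clears it immediately.
"""

import numpy as np

from devibe import (
    AlgoParams,
    false_positive_fraction,
    ghost_scenario,
    run_devb,
    run_vibe,
)

scene = ghost_scenario(64, 64, 60, seed=0)
params = AlgoParams()  # N=20, R=20, lambda=2, phi=16, tau=2
region = scene.regions["ghost"]

devb = run_devb(scene.frames, params)
vibe = run_vibe([f.color for f in scene.frames], params)

for name, result in (("ViBe", vibe), ("DEVB", devb)):
    fp = [
        false_positive_fraction(result.masks[t], scene.frames[t].ground_truth, region)
        for t in range(1, 60)
    ]
    print(
        f"{name}: ghost-region FP fraction, frame 2 = {fp[0]:.3f}, "
        f"mean frames 10-30 = {np.mean(fp[8:29]):.4f}"
    )
print(f"DEVB ghost pixels reclassified in frame 2: {devb.ghost_reclassified[1]}")
print("FP fraction ~1 means the whole departed footprint is still (wrongly)")
print("reported as a moving object; ~0 means the ghost was eliminated.")
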