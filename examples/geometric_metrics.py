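"""Compare two segmentations of one structure with overlap and distance metrics.

Builds a synthetic pelvic phantom, perturbs its CTV the way an
auto-segmentation model errs, and prints DSC, JC, and the classic /
95th-percentile Hausdorff distances between the two contours.
"""

import contoureval as ce
from contoureval.phantoms import PerturbationSpec, StructurePerturbation

image, manual = ce.generate_phantom(seed=7)
spec = PerturbationSpec(per_structure={
    "CTV": StructurePerturbation(shift_mm=(2, 2, 2), boundary_noise_mm=2.5)})
auto = ce.perturb_structures(manual, spec, seed=8)

a, b = manual["CTV"], auto["CTV"]
print(f"CTV volume: manual {a.volume_cc:.1f} cc, auto {b.volume_cc:.1f} cc")
print(f"DSC   = {ce.dice(a, b):.3f}   (1 = complete overlap)")
print(f"JC    = {ce.jaccard(a, b):.3f}   (intersection over union)")
print(f"HD    = {ce.hausdorff(a, b, 100):.2f} mm (largest surface separation)")
print(f"95%HD = {ce.hausdorff(a, b, 95):.2f} mm (ignores the worst 5% of surface points)")
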