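"""Micro-CT new-bone volumetry on a synthetic scan with known truth.

Emulates a 50 um reconstruction of a scaffold patch containing new-bone
deposits (some apposed to the ceramic lattice beams), then runs the
segmentation procedure: median filter, dual thresholding (bone 1800-5300,
ceramic >= 5300), +200 um ceramic offset, Boolean subtraction, and
partitioning between the frame and lattice envelopes.
"""

from sgbr.image import ImageVolume
from sgbr.synthetic import make_ct_phantom, make_ct
from sgbr.ctseg import segment_scan

phantom = make_ct_phantom(seed=7)
scan, truth = make_ct(phantom.labels, seed=7)

result = segment_scan(
    scan,
    ImageVolume(phantom.masks["frame"], phantom.labels.spacing),
    ImageVolume(phantom.masks["lattice_envelope"], phantom.labels.spacing),
    ImageVolume(phantom.masks["native_bone"], phantom.labels.spacing))

truth_cm3 = (truth.values == 4).sum() * phantom.labels.voxel_volume / 1000.0
recovered = sum(result.volumes_cm3.values())
print("new-bone volumes (cm^3):")
for region, v in result.volumes_cm3.items():
    print(f"  {region:15s} {v:.5f}")
print(f"  total recovered  {recovered:.5f}")
print(f"  ground truth     {truth_cm3:.5f}")
print(f"  relative error   {abs(recovered - truth_cm3) / truth_cm3:.1%}")
print("The +200 um offset removes the ceramic partial-volume halo that")
print("would otherwise be miscounted as new bone.")
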