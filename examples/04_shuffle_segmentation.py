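"""Shuffle-subtraction segmentation of enhancing pannus on a phantom.

Generates a digital knee phantom, simulates pre/post-contrast images
with a 1-voxel residual misregistration, and compares simple vs shuffle
subtraction before Otsu thresholding into the VEP mask.
"""

import numpy as np

from synodce.segmentation import (ROILabelMap, ShuffleDifference,
                                  build_vep_mask, shuffle_subtract)
from synodce.synthetic import (AcquisitionSpec, PhantomSpec, generate_phantom,
                               generate_subject_images)

small = dict(grid_shape=(32, 32, 8), voxel_size=(5.0, 5.0, 4.0))
phantom = generate_phantom(PhantomSpec(enhancing_fraction=0.5, **small), seed=1)
study = generate_subject_images(phantom, AcquisitionSpec(**small), None,
                                haematocrit=0.42, seed=2)

pre_shifted = np.roll(study.pre, 1, axis=0)   # residual motion between scans
simple = study.post - pre_shifted
shuffled = shuffle_subtract(pre_shifted, study.post)

bg = study.roi_labels == 0
print(f"background |difference|, simple : {np.abs(simple[bg]).mean():6.2f}")
print(f"background |difference|, shuffle: "
      f"{np.abs(shuffled.diff[bg]).mean():6.2f}")

roi = ROILabelMap(labels=np.where((study.roi_labels >= 1)
                                  & (study.roi_labels <= 7),
                                  study.roi_labels, 0),
                  voxel_size=small["voxel_size"])
vep = build_vep_mask(shuffled, roi)
true_ml = (phantom.enhancing & phantom.synovial_mask()).sum() * 0.1
print(f"VEP volume: {vep.volume_ml['whole_joint']:.1f} mL "
      f"(ground truth enhancing volume {true_ml:.1f} mL)")
# The shuffle transform absorbs the 1-voxel misregistration that simple
# subtraction turns into edge artefact, so Otsu thresholds enhancement
# rather than motion.
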