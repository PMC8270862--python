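"""Extended Tofts forward simulation and voxelwise fit.

Simulates a noisy tissue concentration curve at osteoarthritis-typical
parameters (Ktrans 0.039 min^-1, ve 0.3, vp 0.02), fits it back, and
reports the recovered parameters and the model-free IAUC60.
"""

import numpy as np

from synodce.aif import AIFParameters, plasma_aif
from synodce.pk import (TissueParams, extended_tofts_forward,
                        fit_extended_tofts_voxel)
from synodce.synthetic import AcquisitionSpec, supersampled_time_grid

acq = AcquisitionSpec()                     # 35 phases, 10 s apart
t_fine, obs_idx = supersampled_time_grid(acq)
cp = plasma_aif(t_fine, hct=0.42,
                params=AIFParameters(bolus_arrival_offset=acq.bolus_arrival_min))

truth = TissueParams(ktrans=0.039, ve=0.30, vp=0.02)
clean = extended_tofts_forward(truth, cp, t_fine)[obs_idx]
rng = np.random.default_rng(0)
noisy = clean + rng.normal(0, clean.max() / 50, clean.size)

res = fit_extended_tofts_voxel(noisy, cp, t_fine, obs_idx=obs_idx)
p = res.params
print(f"truth     : Ktrans 0.0390 min^-1, ve 0.300, vp 0.0200")
print(f"recovered : Ktrans {p.ktrans:.4f} min^-1, ve {p.ve:.3f}, "
      f"vp {p.vp:.4f}")
print(f"IAUC60    : {res.iauc60:.2f} mM.s  (bolus arrival "
      f"{res.bolus_arrival * 60:.0f} s, plausible={res.plausible})")
# Ktrans is the plasma->interstitium transfer constant; at SNR 50 it is
# recovered to within a few percent, consistent with its good test-retest
# repeatability relative to ve and vp.
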