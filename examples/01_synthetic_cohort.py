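"""Generate a small synthetic paired fundus/OCT cohort and inspect it.

Each patient contributes a 2D fundus image and a 3D OCT volume rendered
from one shared latent vector, plus clinical-style labels (BCVA and CST
analogs, a fluid biomarker, disease class, injection count, treatment-need
category, conversion outcome).
"""

import numpy as np

from retinapair import synthdata as sd

cfg = sd.SyntheticCohortConfig(n_patients=8, visits_per_patient=(1, 2), seed=1)
scans = sd.generate_cohort(cfg)
manifest = sd.cohort_manifest(scans)

print(manifest[["patient_id", "eye", "visit", "vendor", "y_bcva", "y_cst",
                "fluid", "disease", "n_inj", "treatment_need"]].to_string(index=False))

s = scans[0]
measured = sd.measure_central_band_thickness(s.oct)
print(f"\nfirst scan: fundus {s.fundus.shape}, OCT {s.oct.shape}")
print(f"CST label {s.labels.y_cst:.2f} voxels vs measured central-band run {measured} voxels")
print("-> the rendered central-band thickness IS the CST label (within 1 voxel).")

# the paired modalities share one latent code: same-eye visits stay close
by_patient = {}
for scan in scans:
    by_patient.setdefault(scan.patient_id, []).append(scan)
two_visits = next(v for v in by_patient.values() if len(v) == 2)
z0, z1 = two_visits[0].latent.value, two_visits[1].latent.value
print(f"latent drift between visits of {two_visits[0].patient_id}: "
      f"{np.linalg.norm(z0 - z1):.3f} (per-visit drift sd 0.1)")
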