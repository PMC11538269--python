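"""The pre-training losses on hand-sized inputs.

Shows the InfoNCE / InfoLOOB relationship (the leave-one-out bound has no
log-N floor), modern Hopfield retrieval at its two limits, and the SimCLR /
BYOL / VICReg baselines.
"""

import numpy as np

from retinapair import objectives as obj

# perfectly aligned orthonormal pairs
A = np.eye(4)
print("aligned orthonormal pairs (n=4, tau=1):")
print(f"  InfoNCE  = {float(obj.info_nce(A @ A.T, 1.0).data):.4f}  (>= 0 always)")
print(f"  InfoLOOB = {float(obj.info_loob(A, A, 1.0).data):.4f}  (negative: positive excluded from denominator)")

# uninformative embeddings: InfoNCE sits at log N
rng = np.random.default_rng(0)
U = rng.normal(size=(64, 1024)); U /= np.linalg.norm(U, axis=1, keepdims=True)
V = rng.normal(size=(64, 1024)); V /= np.linalg.norm(V, axis=1, keepdims=True)
print(f"\nrandom unit embeddings (n=64): InfoNCE = {float(obj.info_nce(U @ V.T, 1.0).data):.3f}"
      f" ~ log 64 = {np.log(64):.3f}")

# Hopfield retrieval limits
stored = np.eye(3)
q = np.array([[0.9, 0.1, 0.0]]); q /= np.linalg.norm(q)
soft = obj.hopfield_retrieve(stored, q, beta=0.0).data
hard = obj.hopfield_retrieve(stored, q, beta=1e4).data
print(f"\nHopfield beta=0   -> normalized stored mean: {np.round(soft, 3)}")
print(f"Hopfield beta=1e4 -> nearest stored pattern:  {np.round(hard, 3)}")

# CLOOB = InfoLOOB on Hopfield-retrieved embeddings, both memories
print(f"\nCLOOB loss on the aligned batch: {float(obj.cloob_loss(A, A, 1.0, 8.0).data):.4f}")

# uni-modal baselines
Z1, Z2 = np.eye(2), np.eye(2)
print(f"NT-Xent, two aligned orthonormal views: {float(obj.nt_xent(Z1, Z2, 1.0).data):.4f}"
      f" = log(1 + 2/e) = {np.log(1 + 2 / np.e):.4f}")
print(f"BYOL, prediction equals target: {float(obj.byol_loss(np.eye(3), np.eye(3)).data):.2e}")
print(f"VICReg, constant batch (variance hinge only): {float(obj.vicreg_loss(np.ones((4, 3)), np.ones((4, 3))).data):.2f}"
      " = 2 * 25 * 0.99")
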