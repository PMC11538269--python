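"""Modality interchange: feed fundus embeddings into a prediction head that
was trained on OCT embeddings from the same multi-modal checkpoint.

Because contrastive pre-training maps corresponding fundus/OCT pairs close
together, the OCT-trained head stays informative on fundus inputs; the
relative performance decay quantifies how interchangeable the modalities are.

Run examples/03_pretrain_and_retrieve.py first.
"""

import os
import sys

from retinapair import downstream as ds
from retinapair import pretrain as pt
from retinapair import workflows as wf
from retinapair.encoders import embed

CKPT = "example_out/clip_checkpoint"
if not os.path.isdir(CKPT):
    sys.exit("checkpoint not found - run examples/03_pretrain_and_retrieve.py first")

cfg = wf.default_demo_config(master_seed=0)
_, manifest, data, split, idx = wf.demo_materials(cfg)
encoders = pt.load_checkpoint(CKPT)["encoders"]

E_oct = {s: embed(data["oct"][idx[s]], encoders["oct3d"], l2norm=False).values for s in idx}
fluid = manifest["fluid"].to_numpy()

task = ds.ProbeTask("fluid_detection", "binary", "fluid")
head, report = ds.linear_probe(
    E_oct["train"], fluid[idx["train"]], E_oct["val"], fluid[idx["val"]],
    E_oct["test"], fluid[idx["test"]], task, ds.ProbeConfig(bootstrap_B=200, seed=0),
)
print(f"fluid detection, OCT embeddings -> head: AUROC {report.metrics['auroc']:.3f}, "
      f"AP {report.metrics['ap']:.3f}")

E_fundus = embed(data["fundus"][idx["test"]], encoders["fundus2d"], l2norm=False).values
ic = ds.interchange_eval(head, E_fundus, fluid[idx["test"]], report.metrics)
print(f"same head, fundus embeddings swapped in: AUROC {ic.swapped_metrics['auroc']:.3f}")
print(f"relative decay: {100 * ic.decay['auroc']:.1f}%")
print("-> an AUROC above 0.5 after the swap means the shared embedding space")
print("   transfers the OCT-defined biomarker signal to the cheaper modality.")
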