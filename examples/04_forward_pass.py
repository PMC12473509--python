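"""One synthetic window through the full multi-task network.

Shows the shape contract at every stage: five (L, d) branch embeddings,
their concatenation F (L, 5d), the bidirectional encoder output H_bi
(L, 2*d_out), and the three scalar predictions.
"""

from facephys.benchmarks import desk_model_config
from facephys.model import MultiTaskModel
from facephys.synthetic import SyntheticConfig, generate_subject, generate_window

config = SyntheticConfig(L=150, seed=2)
sample = generate_window(generate_subject(config, 0), cog_state=1,
                         config=config, window_index=0)
batch = {k: v[None] for k, v in sample.tensors.items()}  # batch of one

model = MultiTaskModel(desk_model_config(depth=3), seed=0)
model.eval()
(hr, rr, cog), inter = model(batch, return_intermediates=True)

for name, feat in inter["branches"].items():
    print(f"branch {name:<9} -> {feat.shape}")
print(f"concatenated F     -> {inter['F'].shape}")
print(f"encoder H_bi       -> {inter['H_bi'].shape}")
print(f"fused vector       -> {inter['h_fused'].shape}")
print(f"\npredictions (untrained weights, so physically arbitrary):")
print(f"  hr={float(hr.data[0]):.2f}  rr={float(rr.data[0]):.2f}  "
      f"cog_prob={float(cog.data[0]):.3f}")
print(f"window truth: hr={sample.labels.hr_bpm:.1f} bpm, "
      f"rr={sample.labels.rr_rpm:.1f} rpm, cog={sample.labels.cog}")
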