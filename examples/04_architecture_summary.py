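"""Build the two-SegNet architecture and verify its layer schedule.

The model is assembled from a 54-row schedule (input, 27 conv stages, five
pool/unpool pairs per sub-network, five concatenations in the second
SegNet).  A real forward pass records every realized output shape, which
must match the schedule row by row.
"""

from consegnet import ModelConfig, build_architecture, count_stages, table_schedule

config = ModelConfig.tiny()  # 64x64 input, width 1/8: same topology, CPU-friendly
model = build_architecture(config)

trace = model.trace_shapes()
schedule = table_schedule(config)
matches = sum(t[2] == s.output_shape for t, s in zip(trace, schedule))
print(f"schedule rows: {len(schedule)}, realized-shape matches: {matches}")
print(f"bottleneck: {trace[10][2]}, output: {trace[-1][2]}")
print("stage counts:", count_stages(model))
print(f"parameters: {model.n_parameters():,}")

# All 54 rows must match; stage counts are 5 pools / 5 unpools per
# sub-network with 5 concatenations (4 skips + the bridge) in the second.
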