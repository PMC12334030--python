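"""Inspect the reference architecture without instantiating it.

Prints the exact learnable-parameter count (closed form, equal to the
instantiated model's enumeration), the per-stage feature shapes for a 96³
crop, and the analytic effective receptive field of the attention's
depthwise cascade.
"""

from lkdanet.network import (count_parameters_closed_form, default_config,
                             effective_receptive_field, stage_shape_table)

cfg = default_config(num_classes=9)   # 8 organs + background
n = count_parameters_closed_form(cfg)
print(f"parameters: {n} ({n / 1e6:.2f} M)")

erf = effective_receptive_field([cfg.branch1, cfg.branch2])
print(f"attention cascade receptive field: {erf} voxels per axis")
# 1 + (5-1)*1 + (7-1)*3 = 23: each output voxel sees a 23^3 neighbourhood
# at depthwise cost, the mechanism that stands in for windowed attention.

print("\nencoder scale ladder for a 96^3 input:")
for row in stage_shape_table(cfg, 96):
    print(f"  stage {row['stage']}  scale {row['scale']:>5}  "
          f"{row['channels']:>4} channels  spatial {row['shape']}")
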