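"""Class-level landscape metrics of a generated landscape.

Generates a small landscape and prints, per land-cover class, the five
class-level statistics: patch count, mean patch area (ha), landscape shape
index (LSI, 1 = maximally compact), largest patch index (LPI, % of the
landscape in the largest patch) and patch cohesion (PCI, connectedness).
"""

from lgraf import Config, CropSpec, generate_landscape
from lgraf.outputs import metrics_table

config = Config(
    setup_type="area",
    prop_agricultural_area=0.3,
    width=50,
    height=50,
    total_road_length=150,
    crops=(CropSpec(1, "oil-palm", 0.5), CropSpec(2, "rubber", 0.5)),
    fill_up_crop=1,
)
result = generate_landscape(config, seed=7)

table = metrics_table(result.grid, seed=result.seed)
print(table.pivot(index="class", columns="metric", values="value").round(3))
# 'others' is the habitat class (non-agricultural cells, roads split its
# patches); crop_1/crop_2 are the per-crop field masks.
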