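"""Generate one smallholder landscape and export all map products.

Builds a 100x100-cell landscape (50 m cells, 2500 ha) with straight
artificial roads, households settling in villages along them, and fields
covering 50% of the landscape split between oil palm and rubber.
"""

from lgraf import Config, CropSpec, run_generate
from lgraf.config import DistributionSpec

config = Config(
    setup_type="area",
    prop_agricultural_area=0.5,
    width=100,
    height=100,
    cell_length_m=50.0,
    total_road_length=500,
    hh_area_dist=DistributionSpec("log-normal", 2.0, 1.0),
    field_size_dist=DistributionSpec("log-normal", 1.0, 0.5),
    crops=(CropSpec(1, "oil-palm", 0.5), CropSpec(2, "rubber", 0.5)),
    fill_up_crop=1,
)

result = run_generate(config, "scratch/demo", seed_override=1)

print(f"households:            {len(result.roster)}")
print(f"villages:              {len(result.villages)}")
print(f"fields:                {len(result.fields)}")
print(f"road cells:            {result.roads.total_road_cells}")
print(f"agricultural fraction: {result.agricultural_fraction:.4f}")
# The agricultural fraction lands just under the configured 0.5: households
# stop once another field would move them further from their expected area.
print("rasters + tables written to scratch/demo/")
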