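"""Effect of household crop specialization on the crop mosaic.

Generates landscapes at increasing specialization levels for oil palm and
reports the realized specialization (share of oil-palm-cultivating
households that grow nothing else) and the number of oil-palm patches:
higher specialization aggregates the crop into fewer patches.
"""

from lgraf import Config, CropSpec, generate_landscape
from lgraf.config import DistributionSpec
from lgraf.crops import realized_specialization
from lgraf.grid import label_patches

for level in (0.0, 0.5, 1.0):
    cfg = Config(
        setup_type="area",
        prop_agricultural_area=0.5,
        width=80,
        height=80,
        total_road_length=320,
        hh_area_dist=DistributionSpec("log-normal", 2.0, 1.0),
        land_use_assignment="household-level-specialization",
        crops=(CropSpec(1, "oil-palm", 0.5, level), CropSpec(2, "rubber", 0.5, 0.0)),
        fill_up_crop=1,
    )
    result = generate_landscape(cfg, seed=11)
    realized = realized_specialization(result.roster, result.fields, 1)
    _, n_patches = label_patches(result.grid.crop_id == 1, 8)
    print(
        f"input specialization {level:.1f} -> realized {realized:.3f}, "
        f"{n_patches} oil-palm patches"
    )
# Realized specialization can exceed the input level: households with a
# single field are specialists by construction.
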