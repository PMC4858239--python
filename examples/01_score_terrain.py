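"""Score a synthetic island for habitability.

Builds the two-valley island (a ridge-split island with a river in each
valley), computes the desirability fields and prints the landscape
summary: how many cells are land/sea/freshwater, how the land splits into
flat and tolerable relief classes, and the range of the site rating R_in
and carrying capacity P_best.
"""

import json

from paleodiff import compute_habitability
from paleodiff.habitability import field_summary
from paleodiff.synthetic import TerrainSpec, make_terrain

spec = TerrainSpec(template="two_valley_island", shape=(50, 50), rng_seed=0)
elev, water = make_terrain(spec)
fields = compute_habitability(elev, water)

print(json.dumps(field_summary(fields), indent=2))
print(
    "\nFlat land rates R_in in [%.2f, %.2f]; tolerable land in [%.2f, %.2f]."
    % (
        fields.R_in[fields.habitable & (fields.land_class == 0)].min(),
        fields.R_in[fields.habitable & (fields.land_class == 0)].max(),
        fields.R_in[fields.habitable & (fields.land_class == 1)].min(),
        fields.R_in[fields.habitable & (fields.land_class == 1)].max(),
    )
)
print("The best cells can sustain up to %.3g persons (P_best)." % fields.P_best.max())
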