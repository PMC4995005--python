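"""Diversity indexes from an OTU count table.

Richness counts the OTUs present; Shannon H' mixes richness and
abundance equity; evenness J' = H'/ln(richness) isolates equity; the
inverse Simpson index 1/D weights abundant OTUs, so rare OTUs barely
move it.
"""

import pandas as pd

from soilgam import diversity_profile, profiles_from_table

even = diversity_profile([25, 25, 25, 25])
skewed = diversity_profile([70, 10, 10, 10])
print("uniform community: ", even)
print("skewed community:  ", skewed)
# Same richness (4), but the skewed community has lower H', J' and 1/D.

long_table = pd.DataFrame(
    {
        "sample_id": ["soil_A"] * 3 + ["soil_B"] * 5,
        "otu_id": ["o1", "o2", "o3", "o1", "o2", "o3", "o4", "o5"],
        "count": [50, 30, 20, 20, 20, 20, 20, 20],
    }
)
print(profiles_from_table(long_table).to_string(index=False))
# soil_B is both richer (5 OTUs) and perfectly even (J' = 1).
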