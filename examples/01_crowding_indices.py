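"""Compute pairwise and higher-order crowding indices for a tiny stem map.

Builds a three-stem chain in which the farthest stem is outside the focal
tree's neighbourhood radius but inside its neighbour's, so it contributes
only through the higher-order channel.
"""

import pandas as pd

from hoiforest import CrowdingConfig, compute_crowding_table

stems = pd.DataFrame(
    {
        "treeID": ["f", "j", "k"],
        "stemID": ["1", "1", "1"],
        "sp": ["oak", "oak", "oak"],
        "gx": [50.0, 52.0, 54.0],
        "gy": [50.0, 50.0, 50.0],
        "dbh": [5.0, 10.0, 20.0],
    }
)

cfg = CrowdingConfig(radius=3.0)
table = compute_crowding_table(stems, 100.0, 100.0, cfg)
print(table[["treeID", "sp", "n_i", "n_h", "n_ii", "n_ih", "n_hi", "n_hh"]].round(3))

# For the focal stem 'f': its only pairwise neighbour is j (dbh 10 at 2 m),
# so n_i = 10/2 = 5.  Stem k (dbh 20 at 4 m) is outside f's 3 m radius but
# 2 m from j, so it initiates a higher-order effect through transmitter j:
# n_ii = 5 * (20/2) = 50.  All heterospecific indices are zero in this
# single-species map.
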