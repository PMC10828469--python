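"""Ordinal chain encoding of chronological age and the pixel-level mask.

Each label bit answers "older than schedule age i?", so the ones always
form a prefix and adjacent ages share every bit but one.
"""

import numpy as np

from egps import AgeSchedule, build_ordinal_mask, encode_ordinal

schedule = AgeSchedule((8, 16, 20, 32))
for age in schedule.ages:
    print(f"{age:>2} months -> {encode_ordinal(age, schedule).bits}")

tissue = np.zeros((6, 6), dtype=np.uint8)
tissue[1:5, 1:5] = 1
mask = build_ordinal_mask(tissue, encode_ordinal(20, schedule))
print("\nordinal mask channel sums for a 20-month tile with 16 tissue px:",
      [int(mask[c].sum()) for c in range(3)])
# Channels 0 and 1 copy the tissue mask (older than 8 and 16 months),
# channel 2 stays empty (not older than 20 months).
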