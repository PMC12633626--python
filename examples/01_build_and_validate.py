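"""Generate a synthetic kidney-like dataset and validate its invariants.

The dataset is the bound triple of the representation: a pale PAS-pink RGB
image, one instance-label channel per observation type (pixel 0 =
background, pixel i = instance i), and one feature table per type whose row
index holds the instance IDs.
"""

import numpy as np

import ftumask as fm

ds, gt = fm.generate_dataset(fm.default_spec(seed=7))

print("channels:", ds.bitmask.names)
for name in ds.bitmask.names:
    ids = fm.instances_in_channel(ds.bitmask[name])
    print(f"  {name}: {len(ids)} instances, ids {ids.tolist()}")

report = fm.validate_dataset(ds, strict=True)
print("validation violations:", len(report))
# 0 violations: every pixel value has a matching table row and vice versa.

# Seed a defect: delete the last glomerulus row, leaving its pixels orphaned.
broken = fm.SegmentationDataset(
    bitmask=ds.bitmask,
    image=ds.image,
    tables={**ds.tables,
            "glomerulus": fm.FeatureTable(
                "glomerulus", ds.tables["glomerulus"].data.iloc[:-1]
            )},
)
for v in fm.validate_dataset(broken):
    print(f"  {v.code} at {v.location}: {v.message}")
# MISSING_TABLE_ROW names the pixel value that lost its feature row.
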