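"""Target-site arithmetic on the printed recognition sequences.

Compares the native I-AniI site with the re-targeted XID (mouse Btk) site,
labels their differences in signed coordinates, and builds the 52 bp
cleavage substrate.
"""

import lhekit as lk
from lhekit.sites import MismatchSet

m = lk.mismatches(lk.ANI_SITE, lk.XID_SITE)
print(f"{lk.ANI_SITE.name}: {lk.ANI_SITE.sequence}")
print(f"{lk.XID_SITE.name}:    {lk.XID_SITE.sequence}")
print(f"differences: {len(m)} -> {m.label}")
# 9 differences; the labels are the positions the enzyme had to be
# re-engineered to read, written as signed offsets from the cleavage center.

clusters = ["-10A-8T", "-6C-5C-4T", "+6T+7G", "+9C+10T"]
print("engineering clusters (structure-informed configuration):", clusters)

variant = lk.apply_mismatches(lk.XID_SITE, MismatchSet.parse("-5T"))
print(f"one-off variant -5T: {variant.sequence}")

span = lk.contains_site(lk.TALE_XID_COMPOSITE, lk.XID_SITE)
print(f"XID site inside the megaTAL composite at {span} (0-based half-open)")

substrate = lk.build_substrate(lk.XID_SITE, flank_length=16, seed=0)
print(f"dsOligo substrate: {len(substrate.sequence)} bp, site at {substrate.site_span}")
# 52 bp: the recognition site centered between two 16 bp primer-binding flanks.
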