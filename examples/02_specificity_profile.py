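"""One-off specificity profiling and the mismatch-tolerance rule.

Generates a synthetic profile whose ground-truth tolerated cells are known,
classifies positions as specific vs degenerate at theta = 0.5, and applies
the combination rule to two-mismatch candidate sites.
"""

import lhekit as lk
from lhekit.simulate import gen_profile
from lhekit.sites import MismatchSet
from lhekit.specificity import classify_positions, predict_tolerance, tolerated_single_mismatches

# designate the cells (position, alternative base) the enzyme tolerates
tolerated = {(-10, "G"), (-8, "A"), (-5, "T"), (5, "C")}
profile, truth = gen_profile(lk.XID_SITE, tolerated, theta=0.5, seed=42)

parts = classify_positions(profile)
print(f"specific positions  ({len(parts['specific'])}):",
      [f"{p:+d}" for p in parts["specific"]])
print(f"degenerate positions ({len(parts['degenerate'])}):",
      [f"{p:+d}" for p in parts["degenerate"]])
# degenerate = at least one alternative base cleaved above 50% of on-target

cells = sorted(tolerated_single_mismatches(profile))
print("tolerated single mismatches:", [f"{p:+d}{b}" for p, b in cells])

for label in ("-10G-8A", "+4T+8G"):
    pred = predict_tolerance(MismatchSet.parse(label), profile)
    rs = ", ".join(f"{r:.2f}" for r in pred.per_entry_r)
    print(f"candidate {label}: {pred.call} (per-mismatch r: {rs})")
# a multi-mismatch site is predicted cleavable only if EVERY constituent
# single mismatch is individually tolerated in the one-off profile
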