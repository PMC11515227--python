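"""Agreement between raters and between tests: kappa, collapsing, Venn counts."""

import numpy as np

from ipbkit import cohen_kappa, collapse_to_binary, venn_counts

# two assessors grading the same 12 funnel plots on the 4-level IPB scale
rater_a = ["no", "no", "mild", "mild", "moderate", "no", "severe", "mild",
           "no", "moderate", "mild", "no"]
rater_b = ["no", "mild", "mild", "no", "severe", "no", "moderate", "mild",
           "mild", "moderate", "no", "no"]

four = cohen_kappa(rater_a, rater_b)
binary = cohen_kappa(collapse_to_binary(rater_a), collapse_to_binary(rater_b))
print(f"4-level kappa = {four.kappa:.3f} on n = {four.n}")
print(f"binary (absent/present) kappa = {binary.kappa:.3f}")
print("Collapsing no/mild vs moderate/severe usually raises agreement: raters "
      "disagree most about adjacent mild grades.\n")

# which meta-analyses each of the four tests flags as showing IPB
sig = {
    "egger_one": {"m1", "m2", "m5"},
    "egger_two": {"m1", "m3", "m5", "m7"},
    "peters_one": {"m1", "m2"},
    "peters_two": {"m1", "m2", "m7"},
}
counts = venn_counts(sig, universe={f"m{i}" for i in range(1, 11)})
for region, n in sorted(counts.items(), key=lambda kv: -kv[1]):
    if n:
        print(f"  {region or 'none'}: {n}")
print("Each region counts meta-analyses flagged by exactly that set of tests; "
      "'none' are flagged by no test.")
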