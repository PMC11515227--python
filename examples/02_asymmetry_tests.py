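"""One- and two-sided Egger and Peters tests on an asymmetric funnel.

The fixture mimics inverse publication bias: the large trials show clear
harm (log OR near 0.7) while the small published trials sit near the null,
as if small trials with significant harm went unpublished.
"""

from ipbkit import classify, egger_test, peters_test
from ipbkit.core import StudyEffect

ses = [0.08, 0.12, 0.18, 0.25, 0.33, 0.42, 0.5, 0.6]
ys = [0.68, 0.62, 0.55, 0.4, 0.28, 0.15, 0.1, -0.05]
studies = [
    StudyEffect(f"t{i + 1}", y, se, n_total=round(4 / se**2),
                events_total=round(0.4 / se**2), nonevents_total=round(3.6 / se**2))
    for i, (y, se) in enumerate(zip(ys, ses))
]

for res in (egger_test(studies), peters_test(studies)):
    one = classify(res, alpha=0.1, sidedness="one").significant
    two = classify(res, alpha=0.1, sidedness="two").significant
    print(f"{res.method}: coef = {res.coef:+.3f}, t = {res.t:+.2f} (df {res.df}), "
          f"p_one = {res.p_one:.4f} ({'sig' if one else 'ns'}), "
          f"p_two = {res.p_two:.4f} ({'sig' if two else 'ns'})")

print("\nA negative coefficient is the IPB signature (small studies closer to "
      "the null); the one-sided p tests that direction specifically at alpha = 0.1.")
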