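"""Log odds ratios from 2x2 safety tables, zero handling, and pooling.

Three trials of a drug with a rare adverse event; one trial saw no events
in the treated arm and gets the 0.5 continuity correction applied to all
four cells.
"""

from ipbkit import ContingencyTable, pool_random, study_effect

tables = [
    ContingencyTable(events_trt=12, total_trt=200, events_ctl=6, total_ctl=200),
    ContingencyTable(events_trt=0, total_trt=50, events_ctl=3, total_ctl=50),
    ContingencyTable(events_trt=9, total_trt=150, events_ctl=5, total_ctl=145),
]

effects = [study_effect(t, f"trial_{i + 1}") for i, t in enumerate(tables)]
for eff in effects:
    print(f"{eff.study_id}: log OR = {eff.y:+.3f} (SE {eff.se:.3f}), "
          f"N = {eff.n_total:.0f}, zero handling = {eff.zero_status.value}")

pooled = pool_random(effects)
print(f"\npooled log OR = {pooled.mu:+.3f} (SE {pooled.se_mu:.3f}), "
      f"tau^2 = {pooled.tau2:.4f} via {pooled.tau2_method}")
print("A positive pooled log OR means more adverse events under treatment; "
      "tau^2 is the between-trial variance of the true effects.")
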