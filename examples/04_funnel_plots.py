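"""The three funnel-plot variants: contour-enhanced, trim-and-fill, sample size.

Writes SVGs under ./funnels_out and a JSON export of the geometry; prints
where each study falls relative to the significance contours.
"""

from pathlib import Path

from scipy import stats

from ipbkit import (
    contour_funnel, export_geometry, render, samplesize_funnel,
    trim_and_fill, trimfill_funnel,
)
from ipbkit.core import StudyEffect

studies = [
    StudyEffect("t1", 0.62, 0.12, 1200, 110, 1090),
    StudyEffect("t2", 0.45, 0.20, 520, 48, 472),
    StudyEffect("t3", 0.10, 0.33, 190, 18, 172),
    StudyEffect("t4", -0.05, 0.41, 120, 12, 108),
    StudyEffect("t5", 0.20, 0.52, 80, 8, 72),
]

out = Path("funnels_out")
out.mkdir(exist_ok=True)

geom = contour_funnel(studies, p_levels=(0.1, 0.05, 0.01))
for s in studies:
    p = 2 * stats.norm.sf(abs(s.y / s.se))
    region = next((f"p < {b.p_level:g}" for b in reversed(geom.contour_bands)
                   if p < b.p_level), "non-significant region")
    print(f"{s.study_id}: log OR {s.y:+.2f}, Wald p = {p:.3f} -> {region}")

render(geom, out / "contour.svg", title="contour-enhanced")
export_geometry(geom, out / "contour.json")

tf = trim_and_fill(studies)
render(trimfill_funnel(studies, tf), out / "trimfill.svg",
       title=f"trim-and-fill (k0 = {tf.k0})")
render(samplesize_funnel(studies), out / "samplesize.svg", title="sample size")
print(f"\nwrote contour.svg, trimfill.svg, samplesize.svg (+ contour.json) to {out}/")
print("Missing studies confined to significant regions suggest IPB rather "
      "than chance asymmetry.")
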