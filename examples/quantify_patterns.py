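"""Pattern quantification: lightness and pattern complexity score (PCS).

Generates the three canonical simulated pattern classes (dark spots,
labyrinth, light spots) and quantifies each: PCS is 1 minus the
area-weighted mean isoperimetric quotient Q = 4*pi*S/L^2 of the pattern's
closed contours, and lightness is the unpigmented area fraction.
"""

from patternblend.metrics import quantify_gray
from patternblend.synth import gen_pattern_images

for kind in ("spots_dark", "labyrinth", "spots_light"):
    binary, gray, threshold = gen_pattern_images(kind, size=(64, 64), seed=2)
    m = quantify_gray(gray, threshold)
    print(f"{kind:12s} lightness={m.lightness:.3f}  pcs={m.pcs:.3f}  elements={m.n_elements}")

print(
    "\nSpots are near-circular (low pcs); the labyrinth has elongated elements"
    "\n(high pcs) and a mid-range lightness — the intermediate-and-transgressive"
    "\nsignature of pattern blending."
)
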