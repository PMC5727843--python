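"""Evaluate the facial feature vocabulary on a landmark set.

Builds the canonical synthetic face, evaluates the full candidate
feature list (distances, angles, areas and scale-free ratios over the
numbered frontal/profile landmark points) and prints a few entries.
Ratio and angle features are unitless and survive any change of image
resolution; distances and areas are in pixels of the source image.
"""

from sasangdx import evaluate_feature_set
from sasangdx.grammar import default_feature_names, parse_feature_spec
from sasangdx.synthetic import template_face

face = template_face()
names = default_feature_names()
fv = evaluate_feature_set(face, names)

print(f"evaluated {len(fv.names)} facial features; "
      f"non-finite: {len(fv.nonfinite)}")
for name in ["FD_43_143", "FVV_47_52_52_50", "FA_53_94_43",
             "(FDH_18_25+FDH_118_125)/2/FDH_18_118", "FArea02/FArea03"]:
    expr = parse_feature_spec(name)
    unit = {0: "deg" if name.lstrip("FP").startswith("A") else "(unitless)",
            1: "px", 2: "px^2"}[expr.pixel_power()]
    print(f"  {name:42s} = {fv[name]:10.4f} {unit}")

# FD_43_143 is the cheek-to-cheek face width; FVV_47_52_52_50 the
# forehead-to-nasion over nasion-to-chin height ratio -- the kind of
# proportion that differs between constitutional types.
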