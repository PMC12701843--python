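"""Convert Bernoulli-based clinical thresholds to PD_A equivalents.

Guideline pressure thresholds are stated in Simplified-Bernoulli terms,
which overestimate by collapsing the velocity profile to its peak; a
multiplicative corrective factor (0.65, estimated for aortic stenosis)
maps them onto the SAW-based PD_A scale.
"""

from aortaflow.pipeline import convert_threshold

for bernoulli in (20.0, 36.0):
    conv = convert_threshold(bernoulli, corrective_factor=0.65)
    print(
        f"Bernoulli threshold {conv.bernoulli_threshold_mmhg:4.0f} mm Hg "
        f"-> PD_A threshold {conv.saw_threshold_mmhg:.1f} mm Hg"
    )
# 20 mm Hg (coarctation guideline) maps to 13 mm Hg of PD_A; the 36 mm Hg
# adult-coarctation average maps to 23.4 mm Hg.
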