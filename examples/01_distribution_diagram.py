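"""Species distribution of the binary Cu(II)/tyrosine system.

Builds the bundled binary model (1 mM Cu, 2 mM Tyr), computes the
distribution diagram over pH 2.5-11.0 and reports where each copper
complex dominates.
"""

import cuspec

model = cuspec.bundled_model("Cu_Tyr")
diagram = cuspec.distribution(model, {"Cu": 1e-3, "Tyr": 2e-3})

for name in ("CuH2(Tyr)", "CuH(Tyr)", "CuH2(Tyr)2", "CuH(Tyr)2", "Cu(OH)2"):
    ph, pct = cuspec.peak(diagram, name)
    print(f"{name:<12} peaks at pH {ph:5.2f} with {pct:5.1f} % of total Cu")

print("\npredominant complex at pH  3.0:", cuspec.dominant_species(diagram, 3.0))
print("predominant complex at pH 10.2:", cuspec.dominant_species(diagram, 10.2))

# The percentages refer to total Cu(II): at every pH the listed complexes
# plus free Cu sum to 100 %.  The acidic diprotonated complex gives way to
# CuH(Tyr) (>70 % near pH 4.8) and finally to the bis-complexes.
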