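"""Developability descriptors of designed chains.

Each designed heavy chain is concatenated with a fixed partner light chain
and scored for isoelectric point (pI) and Kyte-Doolittle hydrophobicity
(GRAVY).
"""

from abopt import concat_with_partner, gravy, isoelectric_point

designs = {
    "candidate": "EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGL",
    "design_basic": "EVQLVESGKGRVQPGGSLRLSCKASGFTFSSYAMSWVRQAPGKGL",
    "design_acidic": "EVQLVESGDGEVQPGGSLRLSCDASGFTFSSYAMSWVRQAPGKGL",
}
partner = "DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKAPK"

print(f"{'design':15s} {'pI':>6s} {'GRAVY':>7s}")
for name, chain in designs.items():
    full = concat_with_partner(chain, partner, design_is_heavy=True)
    print(f"{name:15s} {isoelectric_point(full):6.2f} {gravy(full):7.3f}")
# pI is the pH of zero net charge (higher = more basic surface at neutral
# pH); GRAVY > 0 indicates an overall hydrophobic sequence.
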