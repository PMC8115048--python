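"""Denitrification bioenergetics coupled to pyruvate oxidation.

Computes the standard transformed Gibbs free energy change (kJ per mol of
electron acceptor, pH 7, 25 C) for each denitrification step and the
complete nitrate -> N2 pathway, from the packaged formation-energy
constants.
"""

from amgkit import thermo

table = thermo.denitrification_table()
print(table.to_string(index=False, float_format=lambda v: f"{v:9.2f}"))
# Every step is exergonic, so partial denitrifiers occupying a single step
# still gain energy; the complete-pathway value equals the chained step sum
# (with the N2O step weighted 1/2 per mol nitrate) by Hess's law.
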