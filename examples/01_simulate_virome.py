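"""Generate a small ground-truthed synthetic virome.

Builds phage-like scaffolds organised into viral populations, half of them
carrying a nitrogen-cycle AMG cassette with an NtcA site upstream, and
prints what was planted — the truth every later analysis stage is checked
against.
"""

from amgkit import synthetic as sy

virome = sy.simulate_virome(seed=42)

print(f"scaffolds: {len(virome.scaffolds)}")
print(f"genes annotated: {len(virome.gene_table)}")
print("populations:", virome.truth.scaffolds["population_id"].nunique())
amgs = virome.gene_table[virome.gene_table["category"] == "amg"]
print("planted AMGs:", ", ".join(amgs["amg_symbol"]))
print("planted NtcA sites:")
print(virome.truth.motifs.to_string(index=False))
# Each NtcA site (GTA-N8-TAC) sits intergenic, upstream of its AMG — the
# arrangement the motif scanner and positional filter are expected to recover.
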