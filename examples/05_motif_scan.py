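"""Scan a scaffold for NtcA-binding sites and apply the positional filter.

NtcA (the cyanobacterial nitrogen regulator) binds GTA-N8-TAC. A plausible
regulatory site must be intergenic or within 10 bp of a gene boundary.
"""

from amgkit import motifs as mo
from amgkit import synthetic as sy

virome = sy.simulate_virome(seed=42)
row = virome.truth.motifs.iloc[0]
scaffold_id = row["scaffold_id"]
sequence = virome.scaffolds[scaffold_id]
genes = virome.gene_table[virome.gene_table["scaffold_id"] == scaffold_id]

hits = mo.apply_positional_filter(
    mo.scan_motif(sequence, scaffold_id=scaffold_id), genes
)
print(f"{scaffold_id}: {len(hits)} GTA-N8-TAC matches")
for hit in hits:
    mark = "PLANTED" if hit.start == row["start"] else ""
    print(f"  {hit.start:>6}-{hit.end:<6} positional_ok={hit.positional_ok} "
          f"{hit.matched_sequence} {mark}")
# The planted upstream site passes the positional filter; chance matches
# landing mid-gene are flagged positional_ok=False and would be discarded.
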