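"""Annotation-confidence ranking (A-E) and N-cycle shortlisting.

Homology evidence against KEGG / UniRef90 / InterPro collapses into one
confidence letter per gene; annotation text is then matched against the
nitrogen-cycle catalog.
"""

import pandas as pd

from amgkit import ranking as rk

hits = [
    rk.HomologyHit("gene1", "KEGG", "K00368", 412, reciprocal=True,
                   annotation_text="copper-containing nitrite reductase"),
    rk.HomologyHit("gene2", "Uniref90", "U123", 220,
                   annotation_text="ferredoxin-nitrite reductase"),
    rk.HomologyHit("gene3", "InterPro", "IPR001", annotation_text="P-loop NTPase"),
    rk.HomologyHit("gene4", "KEGG", "K99999", 45, annotation_text="hypothetical"),
]
print(rk.rank_table(hits).to_string(index=False))

annotations = pd.DataFrame(
    {
        "query_id": ["gene1", "gene2", "gene3"],
        "annotation_text": [
            "copper-containing nitrite reductase",
            "ferredoxin-nitrite reductase",
            "P-loop NTPase",
        ],
    }
)
print("N-cycle flags:", rk.flag_n_cycle(annotations))
# gene1 (rank A, strong reciprocal KEGG evidence) and gene2 (rank C) match
# the nirK and nirA catalog entries; gene3 and gene4 carry no N-cycle signal.
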