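"""Viral triage: size gates, classifier rules, and the 10-kb reporting gate.

Classifier outputs (VirSorter-style category, VirFinder-style score/p) come
in as a table; the triage rule decides which scaffolds count as viral and
which are large enough to report AMGs from.
"""

from amgkit import triage as tr

features = [
    tr.ScaffoldFeatures("big_cat2", 12400, virsorter_category=2),
    tr.ScaffoldFeatures("mid_score", 8000, virfinder_score=0.95, virfinder_p=0.01),
    tr.ScaffoldFeatures("small_circular", 1800, circular=True,
                        virfinder_score=0.92, virfinder_p=0.03),
    tr.ScaffoldFeatures("weak_score", 12000, virfinder_score=0.85, virfinder_p=0.01),
]
table = tr.triage_table(features)
print(table.to_string(index=False))
# big_cat2 is viral and reportable (>10 kb, category 2); mid_score and
# small_circular are viral but below the 10-kb reporting gate; weak_score
# fails the 0.9 score threshold and is not viral at all.
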