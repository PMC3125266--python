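"""Alignment-table mining: best hits, reciprocal-pair HSP patterns, GC
accounting and contamination triage.

Two contigs whose HSPs are disjoint on both sequences fit the splice-variant
or pre-mRNA/mRNA pattern: the intron present in one contig cannot align to
the other, splitting the alignment in two.
"""

import pandas as pd

from titmine.homology import (
    best_hit, classify_pair, gc_content, genus_triage, load_genus_groups, welch_t,
)
from titmine.io import OUTFMT6_COLUMNS


def rec(**kw):
    base = {"qseqid": "v1", "sseqid": "v2", "pident": 98.0, "length": 200,
            "mismatch": 2, "gapopen": 0, "qstart": 1, "qend": 200,
            "sstart": 1, "send": 200, "evalue": 1e-30, "bitscore": 350.0}
    base.update(kw)
    return base


hits = pd.DataFrame([rec(sseqid="geneA", evalue=1e-30, bitscore=350),
                     rec(sseqid="geneB", evalue=1e-8, bitscore=120)],
                    columns=OUTFMT6_COLUMNS)
print("best hit for v1:", best_hit(hits).loc[0, "sseqid"],
      "(lowest e-value wins; e-values above 1e-5 are discarded)")

# intron-retention pattern: contig v1 keeps an intron, v2 is spliced
pair = pd.DataFrame([rec(qstart=1, qend=200, sstart=1, send=200),
                     rec(qstart=500, qend=700, sstart=201, send=400)],
                    columns=OUTFMT6_COLUMNS)
cls = classify_pair(pair)
print(f"reciprocal pair v1/v2: {cls.n_hsps} HSPs, pattern = {cls.pattern}")
print("  (disjoint on both sequences: one contig likely retains an intron)\n")

gc, amb = gc_content("ATGCGCGCATNNAT")
print(f"GC fraction {gc:.3f} over unambiguous bases; "
      f"ambiguous fraction {amb:.3f}")

groups = load_genus_groups()
for genera in (["Taeniopygia", "Populus"], ["Populus", "Sorghum"], []):
    print(f"hits to {genera or 'nothing'} -> {genus_triage(genera, groups)}")

t, df, p = welch_t([14] * 20 + [10, 18], [52] * 20 + [40, 60])
print(f"\nread-depth contrast (pre-mRNA-like vs mRNA-like contigs): "
      f"t={t:.2f}, df={df:.1f}, p={p:.2g}")
print("  (unequal-variance two-sample t: lower depth for unspliced contigs)")
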