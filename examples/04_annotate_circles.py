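"""Annotate circles against gene / transposable-element / cCRE tracks.

A circle overlapping any single gene by more than 75 bp (strictly) is
flagged as an "eccGene".
"""

from eccv import AnnotationTrack, EccRecord, overlap_annotate
from eccv.annotate import Feature

genes = AnnotationTrack("gene", [
    Feature("chr1", 1200, 2600, "ZMYM6"),
    Feature("chr1", 3000, 3075, "TINY"),
])
tes = AnnotationTrack("transposable_element", [
    Feature("chr1", 900, 1300, "AluY", "SINE"),
])
ccres = AnnotationTrack("cCRE", [
    Feature("chr1", 2500, 2700, "EH38E001", "distal enhancer"),
])

circles = [
    EccRecord("chr1", 1000, 2000, 10, 0.45, "demo"),   # 800 bp into ZMYM6
    EccRecord("chr1", 2950, 3150, 8, 0.40, "demo"),    # 75 bp of TINY: not enough
]
anns = overlap_annotate(circles, [genes, tes, ccres])

for rec, ann in zip(circles, anns):
    print(f"{rec.chrom}:{rec.start}-{rec.end}")
    for cls, hits in ann.hits.items():
        for h in hits:
            print(f"  {cls}: {h.name} ({h.subclass or '-'}), overlap {h.overlap_bp} bp")
    print(f"  eccGene: {ann.is_ecc_gene} {ann.ecc_gene_names}")
print("-> the first circle is an eccGene (800 bp > 75 bp of ZMYM6); the second")
print("   overlaps a gene by exactly 75 bp, which does NOT qualify (rule is strict).")
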