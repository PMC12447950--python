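"""Annotate regulatory elements in orthologous promoter fragments.

Aligns short synthetic orthologue sequences (labelled with real species
names but invented sequence), annotates bipartite Ybx1 DNA-binding sites
and the DLE RNA element with its CCA-N6-TGG stem-loop, and asks which
species retain the bipartite site under the reference feature's columns.
"""

from regennet import elements as el

# synthetic stand-ins for a promoter fragment around a start codon
orthologues = {
    "D_rerio":    "TTGAGCACCCATTTGGATGGCAACGATGATGGCT",
    "C_carpio":   "TTGAGCACCCATTTGGATGGCAACGATGATGACT",
    "C_auratus":  "TTGAGCATCCATTTGGATGGCAACGATGATGGCT",
    "M_musculus": "TTGAGTACCCATTTGGATCGCATCGTTGATGGCT",
}

ref = "D_rerio"
for ann in el.annotate_elements(ref, orthologues[ref]):
    print(f"{ann.feature:15s} [{ann.start:2d}, {ann.end:2d})  {ann.matched}")

aln = el.align_orthologs(orthologues)
print("\nalignment:")
for sid in aln.ids:
    print(f"  {sid:11s} {aln.row(sid)}")

# re-test the bipartite consensus under the reference site's columns
site = next(a for a in el.annotate_elements(ref, orthologues[ref])
            if a.feature == "bipartite_site" and a.matched == "CAACGATG")
row = aln.row(ref)
# map sequence positions to alignment columns
cols = [i for i, ch in enumerate(row) if ch != "-"]
# the concrete site variant (CAAC half + GATG reverse-complement half)
# with its spacer tolerance; the fully degenerate CNNC/GNNG class is too
# permissive to be informative across species
pattern = "CAAC[ACGTN]{0,10}GATG" 
calls = el.conservation_call(aln, ref, cols[site.start],
                             cols[site.end - 1] + 1, pattern)
print("\nbipartite site present in:",
      ", ".join(s for s, ok in calls.items() if ok) or "none")
# Species whose aligned segment still matches the degenerate site pattern
# are called as retaining the element.
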