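"""Generate a synthetic multi-cultivar triploid dataset with known truth.

Builds three autotriploid (AAA) reference cultivars and one allotriploid
(ABB) cultivar carrying two designed homoeologous exchanges, then prints
what the generator produced.  Every output is a pure function of the seed.
"""

from allohe import CultivarDesign, GenomeLayout
from allohe.layout import HEEvent
from allohe.simulate import simulate_cultivar_dataset

designs = [
    CultivarDesign("auto1", "AAA"),
    CultivarDesign("auto2", "AAA"),
    CultivarDesign("auto3", "AAA"),
    CultivarDesign(
        "allo1",
        "ABB",
        he_events=[
            HEEvent("chr04", 20, 49, 1),   # interstitial B1:A2 (30 genes)
            HEEvent("chr11", 70, 99, 3),   # terminal B3:A0 (30 genes)
        ],
    ),
]
layout = GenomeLayout(n_chromosomes=11, genes_per_chromosome=100, snps_per_gene=5)
ds = simulate_cultivar_dataset(designs, layout=layout, seed=1, n_effect_genes=40)

print(f"gene models:       {len(ds.gene_models)} genes on {layout.n_chromosomes} chromosomes")
print(f"SNP catalogue:     {len(ds.catalogue)} sites "
      f"({(ds.catalogue['snp_class'] == 'b_diagnostic').mean():.0%} B-diagnostic)")
print(f"count matrix:      {ds.counts.shape[0]} genes x {ds.counts.shape[1]} samples")
print(f"designed effects:  {len(ds.truth.de_effects)} genes "
      f"({sum(1 for v in ds.truth.redundancy.values() if v == 'compensated')} compensated)")
dosage = ds.truth.gene_dosage["allo1"]
print("allo1 dosage classes (genes per B:A class):")
print(dosage.groupby(["b_dose", "a_dose"]).size().to_string())
# The B2:A1 bulk is the unrecombined ABB baseline; the 30-gene B1:A2 and
# B3:A0 blocks are the designed exchanges the analysis should recover.
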