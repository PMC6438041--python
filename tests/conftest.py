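"""Shared fixtures: seeded synthetic datasets reused across the suite."""

import pandas as pd
import pytest

from allohe import (
    CultivarDesign,
    GenomeLayout,
    NoiseModel,
    SnpTable,
    filter_a_polymorphic,
    frequency_track,
)
from allohe.layout import AneuploidyEvent, HEEvent
from allohe.simulate import simulate_cultivar_dataset


def merge_with_panel(ds, cultivar):
    """Join one cultivar's SNP table with the AAA panel cultivars' depths.

    Returns (merged SnpTable, panel sample names, cultivar sample names).
    """
    aaa = [d.name for d in ds.designs if d.genome_group == "AAA"]
    t = ds.allele_depths[cultivar]
    panel = [ds.allele_depths[c] for c in aaa]
    merged = SnpTable(
        sites=t.sites,
        ref_depth=pd.concat([t.ref_depth] + [p.ref_depth for p in panel], axis=1),
        alt_depth=pd.concat([t.alt_depth] + [p.alt_depth for p in panel], axis=1),
    )
    panel_samples = [s for p in panel for s in p.samples]
    return merged, panel_samples, t.samples


def cultivar_track(ds, cultivar, **filter_kwargs):
    """Filtered B-allele frequency track for one cultivar of a dataset."""
    merged, panel, own = merge_with_panel(ds, cultivar)
    res = filter_a_polymorphic(merged, panel, **filter_kwargs)
    return frequency_track(res.retained, own)


@pytest.fixture(scope="session")
def recombined_abb():
    """Eleven-chromosome dataset with one recombined ABB cultivar.

    ``allo1`` carries the classic pattern: interstitial B1:A2 exchanges on
    chromosomes 4 and 9, a terminal B3:A0 on chromosome 4 and B3:A0 at
    both ends of chromosome 11.  ``allo2`` is unrecombined but has lost
    one chromosome-8 copy (whole-chromosome disomy).
    """
    layout = GenomeLayout(n_chromosomes=11, genes_per_chromosome=100, snps_per_gene=5)
    designs = [
        CultivarDesign("auto1", "AAA"),
        CultivarDesign("auto2", "AAA"),
        CultivarDesign("auto3", "AAA"),
        CultivarDesign(
            "allo1",
            "ABB",
            he_events=[
                HEEvent("chr04", 20, 49, 1),
                HEEvent("chr04", 70, 99, 3),
                HEEvent("chr09", 30, 69, 1),
                HEEvent("chr11", 0, 19, 3),
                HEEvent("chr11", 80, 99, 3),
            ],
        ),
        CultivarDesign(
            "allo2",
            "ABB",
            aneuploidy_events=[AneuploidyEvent("chr08", lost_subgenome="B")],
        ),
    ]
    return simulate_cultivar_dataset(
        designs, layout=layout, noise=NoiseModel(), seed=42, n_effect_genes=40
    )


@pytest.fixture(scope="session")
def expression_dataset():
    """Flat-genome dataset sized for DE and PIE checks (800 genes)."""
    layout = GenomeLayout(n_chromosomes=4, genes_per_chromosome=200)
    designs = [
        CultivarDesign("auto1", "AAA"),
        CultivarDesign("auto2", "AAA"),
        CultivarDesign("auto3", "AAA"),
        CultivarDesign("allo1", "ABB"),
    ]
    return simulate_cultivar_dataset(
        designs, layout=layout, seed=7, n_effect_genes=80, effect_log2fc=3.0
    )
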