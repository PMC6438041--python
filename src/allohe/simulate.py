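"""Synthetic triploid cultivar datasets with known genome structure.

The generator emulates the statistical structure the downstream analysis
assumes: a reference genome carrying B-subgenome-diagnostic SNP sites,
A-lineage polymorphic sites and rare cultivar-private mutations; triploid
(and locally disomic) allele-depth sampling, where the alternate-read
fraction at a diagnostic site with B dose ``d`` and local ploidy ``P`` is
binomial around ``(1-eps)*d/P + eps*(1-d/P)``; and negative-binomial
expression counts in which B-genome presence shifts designated genes by a
known log2 fold change, optionally compensated by a paralog.

All functions are pure in ``(configuration, seed)``; no global RNG state
is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import (
    CultivarDesign,
    GenomeLayout,
    NoiseModel,
    TruthSet,
    chrom_name,
)

SNP_CLASSES = ("b_diagnostic", "a_polymorphic", "private")
_NUCS = np.array(list("ACGT"))

from .snptable import SnpTable


def _gene_id(chrom: str, gi: int) -> str:
    return f"{chrom}g{gi:04d}"


# ----------------------------------------------------------------------
def simulate_genome(
    layout: GenomeLayout,
    seed: int,
    class_proportions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    b_shared_fraction: float = 0.75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate gene models and a SNP site catalogue.

    Returns
    -------
    gene_models :
        ``gene_id, chrom, start, end`` with 1-based inclusive coordinates,
        non-overlapping and sorted within each chromosome.
    catalogue :
        One row per SNP site: ``chrom, pos, gene_id, gene_index, snp_class,
        b_subclass, a_alt_dose, ref_allele, alt_allele``.  ``snp_class`` is
        one of ``b_diagnostic`` (difference between the B lineage and all A
        genomes), ``a_polymorphic`` (segregating within the A lineage) or
        ``private`` (cultivar-specific mutation, owner assigned
        downstream).  Diagnostic sites subdivide into ``shared`` variants
        carried by every B copy (alternate dose = local B dose) and
        ``hemi`` variants specific to one B subgenome (alternate dose = 1
        wherever any B copy is present); the latter produce the residual
        1/3 mode seen in unrecombined two-B regions.  ``a_alt_dose`` gives,
        for A-polymorphic sites, the number of alternate-bearing A copies
        per full A complement; the value 3 marks reference-private
        variants fixed in all non-reference lineages (alternate on every
        copy of every cultivar), which appear at frequency 1 before
        filtration and are removed by it.
    """
    if not math.isclose(sum(class_proportions), 1.0, abs_tol=1e-9):
        raise ValueError("class proportions must sum to 1")
    if not 0.0 <= b_shared_fraction <= 1.0:
        raise ValueError("b_shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    gene_rows = []
    for chrom in layout.chromosomes:
        for gi in range(layout.genes_per_chromosome):
            start = gi * layout.gene_spacing + 1
            end = start + layout.gene_length - 1
            gene_rows.append([_gene_id(chrom, gi), chrom, gi, start, end])
    gene_models = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "gene_index", "start", "end"]
    )

    snp_rows = []
    for row in gene_models.itertuples(index=False):
        n = rng.poisson(layout.snps_per_gene)
        if n == 0:
            continue
        n = min(n, layout.gene_length)
        offsets = np.sort(
            rng.choice(layout.gene_length, size=n, replace=False)
        )
        classes = rng.choice(len(SNP_CLASSES), size=n, p=class_proportions)
        subclasses = rng.choice(
            ["shared", "hemi"], size=n, p=[b_shared_fraction, 1.0 - b_shared_fraction]
        )
        a_doses = rng.choice([1, 2, 3], size=n, p=[0.6, 0.25, 0.15])
        refs = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        for off, cls, sub, ad, r, sh in zip(
            offsets, classes, subclasses, a_doses, refs, alt_shift
        ):
            name = SNP_CLASSES[cls]
            snp_rows.append(
                [
                    row.chrom,
                    row.start + int(off),
                    row.gene_id,
                    row.gene_index,
                    name,
                    sub if name == "b_diagnostic" else "",
                    int(ad) if name == "a_polymorphic" else 0,
                    _NUCS[r],
                    _NUCS[(r + sh) % 4],
                ]
            )
    catalogue = pd.DataFrame(
        snp_rows,
        columns=[
            "chrom",
            "pos",
            "gene_id",
            "gene_index",
            "snp_class",
            "b_subclass",
            "a_alt_dose",
            "ref_allele",
            "alt_allele",
        ],
    )
    return gene_models, catalogue


def assign_private_owners(
    catalogue: pd.DataFrame, cultivar_names: list[str], seed: int
) -> pd.DataFrame:
    """Assign each private-mutation site to one owner cultivar (uniformly)."""
    rng = np.random.default_rng(seed)
    out = catalogue.copy()
    out["private_owner"] = ""
    mask = out["snp_class"] == "private"
    out.loc[mask, "private_owner"] = rng.choice(cultivar_names, size=int(mask.sum()))
    return out


# ----------------------------------------------------------------------
def _alt_probability(
    dose: np.ndarray, ploidy: np.ndarray, eps: float
) -> np.ndarray:
    frac = dose / ploidy
    return (1.0 - eps) * frac + eps * (1.0 - frac)


def simulate_allele_depths(
    design: CultivarDesign,
    catalogue: pd.DataFrame,
    noise: NoiseModel,
    seed: int,
    layout: GenomeLayout | None = None,
) -> SnpTable:
    """Sample per-replicate ref/alt read depths for one cultivar.

    At each site the total depth is negative-binomial with mean
    ``noise.mean_depth``; the alternate depth is binomial with success
    probability ``(1-eps)*d/P + eps*(1-d/P)`` where ``d`` is the alternate
    dose carried by this cultivar at the site and ``P`` the local ploidy.
    Replicates are drawn independently.
    """
    layout = layout or GenomeLayout()
    rng = np.random.default_rng(seed)
    dosage = design.gene_dosage(layout)
    merged = catalogue.merge(dosage, on=["chrom", "gene_index"], how="left")
    if merged["b_dose"].isna().any():
        raise ValueError("catalogue addresses genes outside the design's layout")

    ploidy = merged["ploidy"].to_numpy(dtype=float)
    b_dose = merged["b_dose"].to_numpy(dtype=float)
    a_dose = merged["a_dose"].to_numpy(dtype=float)
    cls = merged["snp_class"].to_numpy()

    sub = merged["b_subclass"].to_numpy()
    dose = np.zeros(len(merged))
    shared = (cls == "b_diagnostic") & (sub == "shared")
    hemi = (cls == "b_diagnostic") & (sub == "hemi")
    dose[shared] = b_dose[shared]
    dose[hemi] = np.minimum(1.0, b_dose[hemi])
    ap = cls == "a_polymorphic"
    a_alt = merged["a_alt_dose"].to_numpy(dtype=float)
    # a_alt_dose == 3 marks reference-private variants fixed in every
    # non-reference lineage: alternate on all copies regardless of subgenome.
    ref_private = ap & (a_alt == 3)
    dose[ref_private] = ploidy[ref_private]
    seg_a = ap & (a_alt < 3)
    dose[seg_a] = np.minimum(a_alt[seg_a], a_dose[seg_a])
    if "private_owner" in merged.columns:
        owned = (cls == "private") & (merged["private_owner"] == design.name).to_numpy()
        dose[owned] = 1.0
    if (dose > ploidy).any():
        raise ValueError("alternate dose exceeds local ploidy")

    p_alt = _alt_probability(dose, ploidy, noise.allele_error_rate)
    shape = noise.depth_dispersion
    p_nb = shape / (shape + noise.mean_depth)

    ref_cols = {}
    alt_cols = {}
    for sample in design.sample_names():
        depth = rng.negative_binomial(shape, p_nb, size=len(merged))
        alt = rng.binomial(depth, p_alt)
        ref_cols[sample] = depth - alt
        alt_cols[sample] = alt

    sites = merged[
        [
            "chrom",
            "pos",
            "gene_id",
            "gene_index",
            "snp_class",
            "b_subclass",
            "ref_allele",
            "alt_allele",
        ]
    ].copy()
    return SnpTable(
        sites=sites,
        ref_depth=pd.DataFrame(ref_cols, index=sites.index),
        alt_depth=pd.DataFrame(alt_cols, index=sites.index),
    )


# ----------------------------------------------------------------------
def simulate_expression(
    designs: list[CultivarDesign],
    truth: TruthSet,
    noise: NoiseModel,
    seed: int,
    layout: GenomeLayout | None = None,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a raw count matrix (genes x samples) plus its sample sheet.

    Counts are NB(mean = baseline * size_factor * 2^(effect * B-presence),
    dispersion phi).  For genes flagged ``compensated`` in the truth set, a
    designated paralog's mean is raised in B-carrying groups so that the
    paralog-group total is equal across genome groups; ``uncompensated``
    genes' paralogs keep flat means.
    """
    layout = layout or GenomeLayout()
    rng = np.random.default_rng(seed)

    gene_ids = [
        _gene_id(chrom, gi)
        for chrom in layout.chromosomes
        for gi in range(layout.genes_per_chromosome)
    ]
    n_genes = len(gene_ids)
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))
    gene_pos0 = {g: i for i, g in enumerate(gene_ids)}
    # paralogs of uncompensated effect genes are flat and low-expressed,
    # so the family-level difference survives aggregation
    for gene, flag in truth.redundancy.items():
        if flag != "uncompensated":
            continue
        group = next((m for m in truth.paralog_map.values() if gene in m), None)
        if not group or len(group) < 2:
            continue
        partners = [m for m in group if m != gene]
        for p in partners:
            baseline[gene_pos0[p]] = 0.1 * baseline[gene_pos0[gene]] / len(partners)
    base_by_gene = dict(zip(gene_ids, baseline))

    # Per-gene multiplier per genome group from the designed B-presence effects.
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    partner_of: dict[str, str] = {}
    for gene, flag in truth.redundancy.items():
        if flag != "compensated":
            continue
        group = next(
            (m for m in truth.paralog_map.values() if gene in m), None
        )
        if group is None or len(group) < 2:
            raise ValueError(f"compensated gene {gene} has no paralog in the map")
        partner_of[gene] = next(m for m in group if m != gene)

    sample_rows = []
    count_cols = {}
    phi = noise.nb_dispersion
    for design in designs:
        has_b = design.genome_group != "AAA"
        mean_vec = baseline.copy()
        if has_b:
            for gene, eff in truth.de_effects.items():
                i = gene_pos[gene]
                new_mean = 0.0 if math.isinf(eff) and eff < 0 else baseline[i] * 2.0**eff
                mean_vec[i] = new_mean
                if gene in partner_of:
                    j = gene_pos[partner_of[gene]]
                    # group total preserved across genome groups
                    mean_vec[j] = base_by_gene[partner_of[gene]] + baseline[i] - new_mean
        for r, sample in enumerate(design.sample_names()):
            sf = float(np.exp(rng.normal(0.0, noise.library_size_sd)))
            mu = mean_vec * sf
            with np.errstate(divide="ignore"):
                p = 1.0 / (1.0 + phi * mu)
            counts = rng.negative_binomial(1.0 / phi, p)
            counts[mu == 0] = 0
            count_cols[sample] = counts
            sample_rows.append([sample, design.name, design.genome_group, r + 1])

    matrix = pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id"))
    sheet = pd.DataFrame(
        sample_rows, columns=["sample", "cultivar", "genome_group", "replicate"]
    )
    return matrix, sheet


# ----------------------------------------------------------------------
@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_cultivar_dataset`."""

    gene_models: pd.DataFrame
    catalogue: pd.DataFrame
    allele_depths: dict[str, SnpTable]
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: TruthSet
    designs: list[CultivarDesign] = field(default_factory=list)
    layout: GenomeLayout = field(default_factory=GenomeLayout)


def _build_paralog_map(
    gene_ids: list[str],
    gene_chrom: dict[str, str],
    rng: np.random.Generator,
    paralog_fraction: float,
    max_group_size: int,
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Randomly partition a fraction of genes into paralog families.

    A minority of families are marked as tandem clusters with a stored
    cluster size (a few exceeding the multicopy-exclusion bound of 10).
    """
    unassigned = list(gene_ids)
    rng.shuffle(unassigned)
    groups: dict[str, list[str]] = {}
    cluster_size: dict[str, int] = {}
    n_target = int(paralog_fraction * len(gene_ids))
    taken = 0
    gid = 0
    idx = 0
    while taken < n_target and idx < len(unassigned):
        size = int(rng.integers(2, max_group_size + 1))
        members = unassigned[idx : idx + size]
        idx += size
        if len(members) < 2:
            break
        gid += 1
        groups[f"OG{gid:05d}"] = sorted(members)
        taken += len(members)
        if rng.random() < 0.08:
            # tandem cluster; ~1/4 of those exceed the multicopy bound
            csize = int(rng.integers(11, 20)) if rng.random() < 0.25 else int(
                rng.integers(2, 10)
            )
            for m in members:
                cluster_size[m] = csize
    return groups, cluster_size


def simulate_cultivar_dataset(
    designs: list[CultivarDesign],
    layout: GenomeLayout | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    class_proportions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    n_effect_genes: int = 60,
    effect_log2fc: float = 3.0,
    frac_compensated: float = 0.5,
    paralog_fraction: float = 0.4,
    max_group_size: int = 4,
) -> SimulatedDataset:
    """End-to-end generation of one multi-cultivar dataset with ground truth.

    Effect genes are split into ``compensated`` (B-presence silences the
    focal gene but a paralog takes over, so the family total is unchanged)
    and ``uncompensated`` (the shift is real at the family level; half the
    uncompensated effects are up, half down).
    """
    layout = layout or GenomeLayout()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    gene_models, catalogue = simulate_genome(layout, int(sub[0]), class_proportions)
    catalogue = assign_private_owners(
        catalogue, [d.name for d in designs], int(sub[1])
    )

    gene_ids = gene_models["gene_id"].tolist()
    gene_chrom = dict(zip(gene_models["gene_id"], gene_models["chrom"]))
    paralog_map, cluster_size = _build_paralog_map(
        gene_ids, gene_chrom, rng, paralog_fraction, max_group_size
    )

    # one effect gene per paralog family at most, so a compensating
    # partner is never itself an effect gene
    eligible_groups = sorted(
        gid
        for gid, members in paralog_map.items()
        if len(members) >= 2 and not any(m in cluster_size for m in members)
    )
    n_comp = int(round(n_effect_genes * frac_compensated))
    n_uncomp = n_effect_genes - n_comp
    if n_comp + n_uncomp > len(eligible_groups):
        raise ValueError(
            "not enough paralog families for the requested effect genes; "
            "increase paralog_fraction or the layout size"
        )
    chosen = rng.choice(eligible_groups, size=n_comp + n_uncomp, replace=False)
    comp_genes = [sorted(paralog_map[g])[0] for g in chosen[:n_comp]]
    uncomp_genes = [sorted(paralog_map[g])[0] for g in chosen[n_comp:]]

    de_effects: dict[str, float] = {}
    redundancy: dict[str, str] = {}
    for g in comp_genes:
        de_effects[g] = -abs(effect_log2fc)
        redundancy[g] = "compensated"
    signs = rng.choice([-1.0, 1.0], size=len(uncomp_genes))
    for g, s in zip(uncomp_genes, signs):
        de_effects[g] = float(s) * abs(effect_log2fc)
        redundancy[g] = "uncompensated"

    dosage = {}
    for d in designs:
        df = d.gene_dosage(layout)
        df["gene_id"] = [
            _gene_id(c, gi) for c, gi in zip(df["chrom"], df["gene_index"])
        ]
        dosage[d.name] = df[["gene_id", "chrom", "gene_index", "b_dose", "a_dose", "ploidy"]]

    truth = TruthSet(
        seed=seed,
        gene_dosage=dosage,
        de_effects=de_effects,
        redundancy=redundancy,
        paralog_map=paralog_map,
        tandem_cluster_size=cluster_size,
    )

    depth_seeds = np.random.default_rng(int(sub[2])).integers(
        0, 2**31 - 1, size=len(designs)
    )
    allele_depths = {
        d.name: simulate_allele_depths(d, catalogue, noise, int(s), layout)
        for d, s in zip(designs, depth_seeds)
    }
    counts, sheet = simulate_expression(
        designs, truth, noise, int(sub[3]), layout
    )
    return SimulatedDataset(
        gene_models=gene_models,
        catalogue=catalogue,
        allele_depths=allele_depths,
        counts=counts,
        sample_sheet=sheet,
        truth=truth,
        designs=designs,
        layout=layout,
    )
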