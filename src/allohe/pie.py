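"""Paralog Inclusive Expression (PIE) analysis.

A differentially expressed gene in a paleopolyploid genome may have
lineage-specific paralogs whose expression compensates for its loss or
silencing, in which case the family-level expression difference — the one
that can matter for the phenotype — vanishes.  PIE sums each focal DEG's
normalised expression with that of its paralogs and re-tests the
aggregate between the same sample groups: the DEG is ``retained`` when
the aggregated difference stays significant with the same sign, and
``overruled`` when the paralogs absorb it.  Focal genes inside large
(> ``max_cluster``-copy) tandem repeat clusters are excluded, since their
members cannot be quantified reliably from short reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import bh_adjust, nb_test

CLASSIFICATIONS = ("retained", "overruled", "excluded_tandem", "no_paralogs")


@dataclass
class ParalogGroup:
    """A lineage-specific paralog family restricted to the focal species."""

    group_id: str
    members: list[str]
    cluster_size: dict[str, int] = field(default_factory=dict)

    def paralogs_of(self, gene: str) -> list[str]:
        if gene not in self.members:
            raise KeyError(f"{gene} is not a member of {self.group_id}")
        return [m for m in self.members if m != gene]


def load_paralog_groups(path, focal_species: str) -> dict[str, ParalogGroup]:
    """Read an orthogroup TSV (``group_id, species, gene_id`` with an
    optional ``cluster_size`` column) keeping focal-species members only.

    Returns a mapping gene id -> its :class:`ParalogGroup`.  A gene listed
    in more than one group is an input error (paralogy here is an
    equivalence grouping).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"group_id", "species", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"orthogroup file needs columns {sorted(required)}")
    focal = df.loc[df["species"] == focal_species]
    if focal.empty:
        raise ValueError(f"focal species {focal_species!r} absent from file")
    dup = focal["gene_id"][focal["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"gene(s) in more than one group: {sorted(dup)}")
    groups: dict[str, ParalogGroup] = {}
    by_gene: dict[str, ParalogGroup] = {}
    for gid, sub in focal.groupby("group_id"):
        sizes = {}
        if "cluster_size" in sub.columns:
            sizes = {
                g: int(c)
                for g, c in zip(sub["gene_id"], sub["cluster_size"])
                if pd.notna(c)
            }
        grp = ParalogGroup(
            group_id=str(gid), members=sorted(sub["gene_id"]), cluster_size=sizes
        )
        groups[str(gid)] = grp
        for g in grp.members:
            by_gene[g] = grp
    return by_gene


def paralog_groups_from_mapping(
    paralog_map: dict[str, list[str]],
    cluster_size: dict[str, int] | None = None,
) -> dict[str, ParalogGroup]:
    """Build the gene -> group index from a plain group-id -> members map
    (the shape stored in a simulated truth set)."""
    cluster_size = cluster_size or {}
    by_gene: dict[str, ParalogGroup] = {}
    seen: dict[str, str] = {}
    for gid, members in paralog_map.items():
        for m in members:
            if m in seen:
                raise ValueError(f"gene {m} in groups {seen[m]} and {gid}")
            seen[m] = gid
        grp = ParalogGroup(
            group_id=gid,
            members=sorted(members),
            cluster_size={m: cluster_size[m] for m in members if m in cluster_size},
        )
        for m in members:
            by_gene[m] = grp
    return by_gene


def write_paralog_groups(
    by_gene: dict[str, ParalogGroup], path, focal_species: str = "musa"
) -> None:
    """Serialise groups to the orthogroup TSV dialect read by
    :func:`load_paralog_groups`."""
    rows = []
    for grp in {g.group_id: g for g in by_gene.values()}.values():
        for m in grp.members:
            rows.append([grp.group_id, focal_species, m, grp.cluster_size.get(m)])
    pd.DataFrame(
        rows, columns=["group_id", "species", "gene_id", "cluster_size"]
    ).sort_values(["group_id", "gene_id"]).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
def tandem_exclusion(
    group: ParalogGroup | None, gene: str, max_cluster: int = 10
) -> bool:
    """True when the focal gene sits in a tandem cluster with strictly
    more than ``max_cluster`` copies (such multicopy clusters are dropped
    from PIE)."""
    if group is None:
        return False
    size = group.cluster_size.get(gene)
    if size is None:
        return False
    return size > max_cluster


def infer_tandem_clusters(
    by_gene: dict[str, ParalogGroup],
    gene_models: pd.DataFrame,
    max_gap: int = 100_000,
) -> None:
    """Approximate tandem clusters as runs of same-group genes within
    ``max_gap`` bp on one chromosome; fills ``cluster_size`` in place for
    groups lacking annotation."""
    coords = gene_models.set_index("gene_id")
    for grp in {g.group_id: g for g in by_gene.values()}.values():
        if grp.cluster_size:
            continue
        placed = [
            (coords.at[m, "chrom"], int(coords.at[m, "start"]), m)
            for m in grp.members
            if m in coords.index
        ]
        placed.sort()
        run: list[str] = []
        prev = None
        runs: list[list[str]] = []
        for chrom, start, m in placed:
            if prev and prev[0] == chrom and start - prev[1] <= max_gap:
                run.append(m)
            else:
                if len(run) > 1:
                    runs.append(run)
                run = [m]
            prev = (chrom, start)
        if len(run) > 1:
            runs.append(run)
        for r in runs:
            for m in r:
                grp.cluster_size[m] = len(r)


def aggregate_expression(
    focal: str, paralogs: list[str], normalized: pd.DataFrame
) -> pd.Series:
    """Element-wise per-sample sum of the focal gene's and its paralogs'
    normalised counts (permutation-invariant in the paralog list)."""
    for g in [focal] + list(paralogs):
        if g not in normalized.index:
            raise KeyError(f"gene {g} missing from the normalised matrix")
    return normalized.loc[[focal] + list(paralogs)].sum(axis=0)


# ----------------------------------------------------------------------
@dataclass
class PieResult:
    gene_id: str
    classification: str
    paralogs: list[str]
    aggregated: pd.Series | None
    aggregated_pvalue: float | None = None
    aggregated_qvalue: float | None = None
    aggregated_logfc: float | None = None
    focal_qvalue: float | None = None
    flag: str = ""


def classify_pie(
    focal: str,
    group: ParalogGroup | None,
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    focal_result: pd.Series | None = None,
    alpha: float = 0.05,
    max_cluster: int = 10,
    dispersion: float | None = None,
) -> PieResult:
    """Classify a single focal DEG; see :func:`pie_table` for the batch
    version whose aggregated q-values are FDR-adjusted jointly."""
    table = pie_table(
        [focal],
        {focal: group} if group is not None else {},
        matrix,
        size_factors,
        group_a,
        group_b,
        focal_results=(
            pd.DataFrame([focal_result]) if focal_result is not None else None
        ),
        alpha=alpha,
        max_cluster=max_cluster,
        dispersion=dispersion,
    )
    row = table.iloc[0]
    paralogs = row["paralogs"].split(",") if row["paralogs"] else []
    return PieResult(
        gene_id=focal,
        classification=row["classification"],
        paralogs=paralogs,
        aggregated=None,
        aggregated_pvalue=row["aggregated_pvalue"],
        aggregated_qvalue=row["aggregated_qvalue"],
        aggregated_logfc=row["aggregated_logFC"],
        focal_qvalue=row["focal_qvalue"],
        flag=row["flag"],
    )


def pie_table(
    degs: list[str],
    by_gene: dict[str, ParalogGroup],
    matrix: pd.DataFrame,
    size_factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    focal_results: pd.DataFrame | None = None,
    alpha: float = 0.05,
    max_cluster: int = 10,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """PIE classification of a set of focal DEGs.

    For every DEG with paralogs outside large tandem clusters, the
    normalised counts of the family are summed per sample, rounded, and
    re-tested with the same NB exact test (common dispersion recomputed on
    the aggregated matrix); q-values are BH-adjusted across the re-tested
    set.  ``retained`` requires aggregated q <= alpha with a fold-change
    sign matching the focal gene's; ``overruled`` otherwise.  A DEG whose
    aggregated vector is all zero is retained with a flag (family absence
    is itself the signal).
    """
    samples = list(group_a) + list(group_b)
    normalized = matrix[samples].div(size_factors[samples], axis=1)

    focal_sign: dict[str, float] = {}
    focal_q: dict[str, float] = {}
    if focal_results is not None:
        for _, r in focal_results.iterrows():
            focal_sign[r["gene_id"]] = float(np.sign(r["logFC"]))
            focal_q[r["gene_id"]] = float(r["qvalue"])

    rows = []
    agg_vectors = {}
    for gene in degs:
        grp = by_gene.get(gene)
        paralogs = grp.paralogs_of(gene) if grp is not None else []
        if not paralogs:
            rows.append([gene, "no_paralogs", "", None, None, None, focal_q.get(gene), ""])
            continue
        if tandem_exclusion(grp, gene, max_cluster):
            rows.append(
                [gene, "excluded_tandem", ",".join(paralogs), None, None, None,
                 focal_q.get(gene), f"cluster_size={grp.cluster_size.get(gene)}"]
            )
            continue
        agg = aggregate_expression(gene, paralogs, normalized)
        agg_vectors[gene] = agg
        rows.append([gene, None, ",".join(paralogs), None, None, None, focal_q.get(gene), ""])

    if agg_vectors:
        agg_matrix = pd.DataFrame(agg_vectors).T
        agg_matrix = np.rint(agg_matrix).astype(int)
        unit = pd.Series(1.0, index=agg_matrix.columns)  # already normalised
        res = nb_test(
            agg_matrix, unit, group_a, group_b, dispersion=dispersion
        ).set_index("gene_id")
        res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
        for row in rows:
            gene = row[0]
            if row[1] is not None or gene not in res.index:
                continue
            r = res.loc[gene]
            row[3], row[4], row[5] = float(r["pvalue"]), float(r["qvalue"]), float(r["logFC"])
            if agg_vectors[gene].sum() == 0:
                row[1] = "retained"
                row[7] = "aggregated_all_zero"
                continue
            sign_ok = True
            if gene in focal_sign and focal_sign[gene] != 0:
                sign_ok = np.sign(r["logFC"]) == focal_sign[gene]
            row[1] = "retained" if (r["qvalue"] <= alpha and sign_ok) else "overruled"

    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "classification",
            "paralogs",
            "aggregated_pvalue",
            "aggregated_qvalue",
            "aggregated_logFC",
            "focal_qvalue",
            "flag",
        ],
    )
    return out
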