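"""Domain types describing simulated triploid genomes and cultivar designs.

Coordinates are 1-based inclusive throughout the package; BED output
converts to 0-based half-open at the boundary.  Chromosomes are labelled
``chr01`` .. ``chrNN``; the reserved label ``chr00`` denotes unanchored
scaffolds, which are excluded from dosage segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

#: Baseline B-subgenome copy number implied by a genome-group label at
#: ploidy 3 (AAA = autotriploid, AAB/ABB = allotriploid).
_BASELINE_B = {"AAA": 0, "AAB": 1, "ABB": 2}

UNANCHORED = "chr00"


def baseline_b_dose(genome_group: str) -> int:
    """Expected whole-genome B dose for a genome group (AAA->0, AAB->1, ABB->2)."""
    try:
        return _BASELINE_B[genome_group]
    except KeyError:
        raise ValueError(
            f"unknown genome group {genome_group!r}; expected one of AAA, AAB, ABB"
        ) from None


def chrom_name(i: int) -> str:
    return f"chr{i:02d}"


@dataclass(frozen=True)
class GenomeLayout:
    """Gene and SNP layout of a simulated genome.

    Parameters
    ----------
    n_chromosomes :
        Number of anchored chromosomes (banana has 11).
    genes_per_chromosome :
        Genes placed on each chromosome, in order, non-overlapping.
    snps_per_gene :
        Mean number of SNP sites per gene (Poisson distributed).
    gene_length :
        Length in bp of each gene interval.
    gene_spacing :
        Distance in bp between consecutive gene starts.
    """

    n_chromosomes: int = 11
    genes_per_chromosome: int = 100
    snps_per_gene: float = 5.0
    gene_length: int = 3_000
    gene_spacing: int = 10_000

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.genes_per_chromosome <= 0:
            raise ValueError("chromosome and gene counts must be positive")
        if self.snps_per_gene <= 0:
            raise ValueError("snps_per_gene must be positive")
        if self.gene_length <= 0 or self.gene_spacing < self.gene_length:
            raise ValueError("gene intervals must be positive and non-overlapping")

    @property
    def chromosomes(self) -> list[str]:
        return [chrom_name(i + 1) for i in range(self.n_chromosomes)]

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome


@dataclass(frozen=True)
class HEEvent:
    """A homoeologous exchange: genes in [start_gene, end_gene] (0-based
    indices within the chromosome, inclusive) switch to ``new_b_dose``."""

    chromosome: str
    start_gene: int
    end_gene: int
    new_b_dose: int


@dataclass(frozen=True)
class AneuploidyEvent:
    """Loss of one chromosome copy over a gene-index interval (or the whole
    chromosome when start/end are None).  Local ploidy drops to 2; the lost
    copy is a B copy when the local B dose allows, else an A copy."""

    chromosome: str
    start_gene: int | None = None
    end_gene: int | None = None
    lost_subgenome: str = "A"  # "A" or "B"


@dataclass
class CultivarDesign:
    """Designed genome structure of one simulated cultivar."""

    name: str
    genome_group: str
    he_events: list[HEEvent] = field(default_factory=list)
    aneuploidy_events: list[AneuploidyEvent] = field(default_factory=list)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        baseline_b_dose(self.genome_group)  # validates
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def sample_names(self) -> list[str]:
        return [f"{self.name}_rep{r + 1}" for r in range(self.n_replicates)]

    def gene_dosage(self, layout: GenomeLayout) -> pd.DataFrame:
        """Per-gene (b_dose, a_dose, ploidy) after applying HE and aneuploidy.

        Returns a frame indexed by gene order with columns
        ``chrom, gene_index, b_dose, a_dose, ploidy``.
        """
        base_b = baseline_b_dose(self.genome_group)
        rows = []
        for chrom in layout.chromosomes:
            for gi in range(layout.genes_per_chromosome):
                rows.append([chrom, gi, base_b, 3])
        df = pd.DataFrame(rows, columns=["chrom", "gene_index", "b_dose", "ploidy"])

        for ev in self.he_events:
            mask = (
                (df["chrom"] == ev.chromosome)
                & (df["gene_index"] >= ev.start_gene)
                & (df["gene_index"] <= ev.end_gene)
            )
            if not mask.any():
                raise ValueError(f"HE event addresses no genes: {ev}")
            if not 0 <= ev.new_b_dose <= 3:
                raise ValueError(f"new_b_dose out of range: {ev}")
            df.loc[mask, "b_dose"] = ev.new_b_dose

        for ev in self.aneuploidy_events:
            mask = df["chrom"] == ev.chromosome
            if ev.start_gene is not None:
                mask &= df["gene_index"] >= ev.start_gene
            if ev.end_gene is not None:
                mask &= df["gene_index"] <= ev.end_gene
            if not mask.any():
                raise ValueError(f"aneuploidy event addresses no genes: {ev}")
            df.loc[mask, "ploidy"] = 2
            if ev.lost_subgenome == "B":
                if (df.loc[mask, "b_dose"] < 1).any():
                    raise ValueError(f"no B copy to lose in part of {ev}")
                df.loc[mask, "b_dose"] = df.loc[mask, "b_dose"] - 1
            else:
                if (df.loc[mask, "b_dose"] > 2).any():
                    raise ValueError(f"no A copy to lose in part of {ev}")

        df["a_dose"] = df["ploidy"] - df["b_dose"]
        if (df["b_dose"] < 0).any() or (df["a_dose"] < 0).any():
            raise ValueError("design produced negative subgenome dose")
        return df


@dataclass
class NoiseModel:
    """Read-depth and count noise parameters for the simulator.

    ``mean_depth`` is the expected per-site, per-replicate read depth
    (negative-binomially distributed with shape ``depth_dispersion``).
    ``allele_error_rate`` is the probability that a read reports the wrong
    allele (sequencing plus mapping error).  ``nb_dispersion`` is the
    per-gene over-dispersion of expression counts (variance =
    mu + phi * mu^2).
    """

    mean_depth: float = 30.0
    depth_dispersion: float = 10.0
    allele_error_rate: float = 0.005
    nb_dispersion: float = 0.05
    library_size_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.allele_error_rate < 0.5:
            raise ValueError("allele_error_rate must be in [0, 0.5)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass
class TruthSet:
    """Ground truth of a simulated dataset, serialisable to JSON.

    ``gene_dosage`` maps cultivar name -> per-gene dosage frame (as produced
    by :meth:`CultivarDesign.gene_dosage`).  ``de_effects`` maps gene id ->
    log2 fold change attributable to B-genome presence.  ``redundancy``
    maps gene id -> "compensated" | "uncompensated".  ``paralog_map`` maps
    group id -> list of member gene ids.
    """

    seed: int
    gene_dosage: dict[str, pd.DataFrame]
    de_effects: dict[str, float] = field(default_factory=dict)
    redundancy: dict[str, str] = field(default_factory=dict)
    paralog_map: dict[str, list[str]] = field(default_factory=dict)
    tandem_cluster_size: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "gene_dosage": {
                name: df.to_dict(orient="list") for name, df in self.gene_dosage.items()
            },
            "de_effects": self.de_effects,
            "redundancy": self.redundancy,
            "paralog_map": self.paralog_map,
            "tandem_cluster_size": self.tandem_cluster_size,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        dosage = {
            name: pd.DataFrame(cols) for name, cols in payload["gene_dosage"].items()
        }
        return cls(
            seed=payload["seed"],
            gene_dosage=dosage,
            de_effects={k: float(v) for k, v in payload["de_effects"].items()},
            redundancy=payload["redundancy"],
            paralog_map=payload["paralog_map"],
            tandem_cluster_size={
                k: int(v) for k, v in payload["tandem_cluster_size"].items()
            },
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthSet):
            return NotImplemented
        if (
            self.seed != other.seed
            or self.de_effects != other.de_effects
            or self.redundancy != other.redundancy
            or self.paralog_map != other.paralog_map
            or self.tandem_cluster_size != other.tandem_cluster_size
            or set(self.gene_dosage) != set(other.gene_dosage)
        ):
            return False
        def canon(df: pd.DataFrame) -> pd.DataFrame:
            return df[sorted(df.columns)].reset_index(drop=True)

        return all(
            canon(self.gene_dosage[k]).equals(canon(other.gene_dosage[k]))
            for k in self.gene_dosage
        )
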