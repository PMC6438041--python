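"""Over/under-representation of DEGs inside dosage-deviating regions.

The null model is the central hypergeometric distribution with fixed
margins: of ``N`` annotated genes, ``K`` lie in a region class and ``n``
are differentially expressed; the number ``k`` of DEGs falling in the
class is tested one-sidedly in each direction.  Tails are accumulated in
log space from the log-pmf, so extreme deviations keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .layout import baseline_b_dose


@dataclass(frozen=True)
class EnrichmentInput:
    """Fixed-margin counts for one (genotype, region class) test."""

    N: int  # population gene count
    K: int  # genes in the region class
    n: int  # DEG count
    k: int  # DEGs in the region class
    genotype: str = ""
    region_class: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError("need 0 <= K <= N and 0 <= n <= N")
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError("need 0 <= k <= min(K, n)")


@dataclass(frozen=True)
class EnrichmentResult:
    input: EnrichmentInput
    expected: float  # n*K/N under the null
    fold: float  # k / expected
    p_over: float  # P(X >= k)
    p_under: float  # P(X <= k)


def hypergeom_region_test(inp: EnrichmentInput) -> EnrichmentResult:
    """One-sided hypergeometric tail probabilities for a region class.

    ``p_over`` is the upper tail P(X >= k) and ``p_under`` the lower tail
    P(X <= k); both include the observed point mass, so they sum to at
    least 1.
    """
    lo = max(0, inp.n + inp.K - inp.N)
    hi = min(inp.K, inp.n)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, inp.N, inp.K, inp.n)
    p_over = float(np.exp(logsumexp(logpmf[support >= inp.k])))
    p_under = float(np.exp(logsumexp(logpmf[support <= inp.k])))
    expected = inp.n * inp.K / inp.N
    fold = inp.k / expected if expected > 0 else float("nan")
    return EnrichmentResult(
        input=inp,
        expected=expected,
        fold=fold,
        p_over=min(p_over, 1.0),
        p_under=min(p_under, 1.0),
    )


def build_enrichment_inputs(
    per_gene: pd.DataFrame,
    deg_set: set[str] | list[str],
    genome_group: str,
    genotype: str = "",
    masked_chromosomes: set[str] | None = None,
    population: str = "assigned",
) -> list[EnrichmentInput]:
    """One :class:`EnrichmentInput` per deviating dosage class.

    ``per_gene`` is the dosage-annotation table (``gene_id, chrom, label``)
    from segmentation; ``deg_set`` the consensus DEG ids.  Genes on
    ``masked_chromosomes`` (aneuploid chromosomes, excluded the way
    chromosome-level losses are excluded from region bookkeeping) are
    removed from every margin.  ``population`` chooses the universe:
    ``"assigned"`` keeps genes with a called dosage (annotated-chromosome
    universe); ``"all"`` keeps every gene in the table, including
    unanchored/uncallable ones (whole-annotation universe).
    """
    masked = masked_chromosomes or set()
    df = per_gene.loc[~per_gene["chrom"].isin(masked)]
    if population == "assigned":
        df = df.loc[~df["label"].isin(["unanchored", "uncallable"])]
    elif population != "all":
        raise ValueError("population must be 'assigned' or 'all'")

    deg_set = set(deg_set) & set(df["gene_id"])
    b = baseline_b_dose(genome_group)
    baseline_label = f"B{b}:A{3 - b}"
    deviating = sorted(
        lab
        for lab in df["label"].dropna().unique()
        if lab not in (baseline_label, "unanchored", "uncallable")
    )
    N = len(df)
    n = len(deg_set)
    is_deg = df["gene_id"].isin(deg_set)
    inputs = []
    for lab in deviating:
        in_class = df["label"] == lab
        K = int(in_class.sum())
        if K == 0:
            continue
        k = int((in_class & is_deg).sum())
        inputs.append(
            EnrichmentInput(
                N=N, K=K, n=n, k=k, genotype=genotype, region_class=str(lab)
            )
        )
    return inputs


def enrichment_report(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat table of enrichment tests, one row per (genotype, class)."""
    return pd.DataFrame(
        {
            "genotype": [r.input.genotype for r in results],
            "region_class": [r.input.region_class for r in results],
            "N": [r.input.N for r in results],
            "genes_in_class": [r.input.K for r in results],
            "degs_total": [r.input.n for r in results],
            "degs_in_class": [r.input.k for r in results],
            "expected": [r.expected for r in results],
            "fold": [r.fold for r in results],
            "p_over": [r.p_over for r in results],
            "p_under": [r.p_under for r in results],
        }
    )
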