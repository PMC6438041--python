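"""Retention of B-subgenome-diagnostic SNPs and B-allele frequency tracks.

The filtration mirrors the logic used to isolate B-genome variants in an
allotriploid mapped against the A reference: any site at which an A-genome
panel sample (AAA cultivars and/or the reference itself) shows the
alternate allele is discarded as A-polymorphic; sites the panel cannot
assess (insufficient depth in every panel sample) are discarded as
unassessable.  What survives is, to a first approximation, specific to the
B subgenome(s), and its pooled alternate-read fraction estimates
``d/P`` for B dose ``d`` at local ploidy ``P``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .snptable import SnpTable

RETAINED = "retained"
REMOVED_POLYMORPHIC = "removed_polymorphic"
REMOVED_UNASSESSABLE = "removed_unassessable"


@dataclass
class FilterResult:
    """Outcome of :func:`filter_a_polymorphic`.

    ``retained`` holds the surviving sites (their ``sites`` frame carries a
    ``filter_status`` audit column); ``audit`` is the per-input-site status
    table satisfying |input| = |retained| + |removed_polymorphic| +
    |removed_unassessable|.
    """

    retained: SnpTable
    audit: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return self.audit["filter_status"].value_counts().to_dict()


def filter_a_polymorphic(
    table: SnpTable,
    a_panel_samples: list[str],
    min_a_depth: int = 10,
    max_a_alt_fraction: float = 0.05,
) -> FilterResult:
    """Remove sites polymorphic (or unassessable) in the A-genome panel.

    A site is removed as polymorphic when any panel sample with depth >=
    ``min_a_depth`` shows an alternate fraction above
    ``max_a_alt_fraction``; removed as unassessable when no panel sample
    reaches ``min_a_depth``.  Enlarging the panel can only shrink the
    retained set.
    """
    if not a_panel_samples:
        raise ValueError("A-panel sample list is empty")
    if min_a_depth < 1:
        raise ValueError("min_a_depth must be >= 1")
    unknown = [s for s in a_panel_samples if s not in table.samples]
    if unknown:
        raise ValueError(f"unknown A-panel sample label(s): {unknown}")

    ref = table.ref_depth[a_panel_samples].to_numpy(dtype=float)
    alt = table.alt_depth[a_panel_samples].to_numpy(dtype=float)
    depth = ref + alt
    assessed = depth >= min_a_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt / depth, 0.0)
    polymorphic = (assessed & (frac > max_a_alt_fraction)).any(axis=1)
    unassessable = ~assessed.any(axis=1)

    status = np.full(table.n_sites, RETAINED, dtype=object)
    status[unassessable] = REMOVED_UNASSESSABLE
    status[polymorphic & ~unassessable] = REMOVED_POLYMORPHIC

    audit = table.sites[["chrom", "pos"]].copy()
    if "gene_id" in table.sites.columns:
        audit["gene_id"] = table.sites["gene_id"]
    audit["filter_status"] = status

    keep = status == RETAINED
    retained = table.subset(keep)
    retained.sites = retained.sites.copy()
    retained.sites["filter_status"] = RETAINED
    return FilterResult(retained=retained, audit=audit)


def b_allele_frequency(
    ref_depths: np.ndarray | list[int], alt_depths: np.ndarray | list[int]
) -> float:
    """Pooled B-allele frequency over a cultivar's replicates at one site.

    Depths are summed before dividing (replicates weighted by evidence,
    not averaged as frequencies).
    """
    ref_sum = float(np.sum(ref_depths))
    alt_sum = float(np.sum(alt_depths))
    total = ref_sum + alt_sum
    if total <= 0:
        raise ZeroDivisionError("pooled depth is zero at this site")
    return alt_sum / total


def frequency_track(
    table: SnpTable, cultivar_samples: list[str]
) -> pd.DataFrame:
    """Per-site pooled B-allele frequency for one cultivar.

    Returns a frame ``chrom, pos, gene_id, gene_index, f, depth`` sorted by
    position within chromosome.  Sites with zero pooled depth are skipped
    with a warning.
    """
    unknown = [s for s in cultivar_samples if s not in table.samples]
    if unknown:
        raise ValueError(f"unknown sample label(s): {unknown}")
    ref = table.ref_depth[cultivar_samples].sum(axis=1)
    alt = table.alt_depth[cultivar_samples].sum(axis=1)
    depth = ref + alt
    zero = depth == 0
    if zero.any():
        warnings.warn(
            f"skipping {int(zero.sum())} site(s) with zero pooled depth",
            stacklevel=2,
        )
    out = table.sites.copy()
    out["f"] = alt / depth.replace(0, np.nan)
    out["depth"] = depth
    out = out.loc[~zero.to_numpy()]
    keep_cols = [
        c
        for c in ("chrom", "pos", "gene_id", "gene_index", "snp_class", "b_subclass", "f", "depth")
        if c in out.columns
    ]
    return (
        out[keep_cols]
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )


def frequency_histogram(
    track: pd.DataFrame,
    n_bins: int = 50,
    min_prominence_fraction: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Histogram of B-allele frequencies with detected modes.

    Returns ``(bin_edges, counts, modes)`` where modes are bin centres of
    local maxima whose peak prominence exceeds
    ``min_prominence_fraction`` of the total site count.  The histogram is
    zero-padded before peak finding so that boundary bars (e.g. the bar at
    frequency 1 produced by fixed differences) register as modes.
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    if track.empty:
        raise ValueError("frequency track is empty")
    f = track["f"].to_numpy(dtype=float)
    counts, edges = np.histogram(f, bins=n_bins, range=(0.0, 1.0))
    padded = np.concatenate([[0], counts, [0]]).astype(float)
    prominence = max(1.0, min_prominence_fraction * len(f))
    peaks, _ = find_peaks(padded, prominence=prominence)
    # a mode must also stand clearly above the typical bin, otherwise the
    # tallest fluctuation of a flat histogram would register
    floor = 2.0 * float(np.median(counts)) + 1.0
    centres = (edges[:-1] + edges[1:]) / 2.0
    modes = [float(centres[p - 1]) for p in peaks if counts[p - 1] >= floor]
    return edges, counts, modes
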