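"""Chromosome dosage segmentation from B-allele-frequency tracks.

Each retained SNP site contributes a binomial observation: at B dose ``d``
and local ploidy ``P`` the alternate-read probability is
``(1-eps)*d/P + eps*(1-d/P)``.  Sites are classified by a windowed
maximum-likelihood grid over candidate doses, adjacent same-dose runs are
merged into segments snapped to gene boundaries, and whole-chromosome (or
per-arm) ploidy is compared between trisomic and disomic models to call
aneuploidy.  A small uniform "outlier" mixture component bounds the
influence of cultivar-private mutations that survive filtration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .layout import UNANCHORED, baseline_b_dose


@dataclass
class SegmentationParams:
    """Tuning knobs for track segmentation and aneuploidy calling."""

    window_snps: int = 25
    min_genes_per_segment: int = 10
    min_snps_per_segment: int = 5
    min_snps_per_chromosome: int = 20
    eps: float = 0.005
    outlier_fraction: float = 0.05
    hemi_fraction: float = 0.25
    disomy_delta_loglik: float = 10.0


@dataclass
class DosageSegment:
    """A chromosome interval of constant inferred subgenome dosage."""

    chromosome: str
    start: int
    end: int
    b_dose: int | None
    ploidy: int
    n_snps: int
    mean_f: float

    @property
    def a_dose(self) -> int | None:
        return None if self.b_dose is None else self.ploidy - self.b_dose

    @property
    def label(self) -> str:
        if self.b_dose is None:
            return "uncallable"
        return f"B{self.b_dose}:A{self.a_dose}"


def _site_loglik(
    alt: np.ndarray,
    depth: np.ndarray,
    ploidy: int,
    eps: float,
    outlier_fraction: float,
    hemi_fraction: float = 0.0,
) -> np.ndarray:
    """Per-site log-likelihood matrix, shape (n_sites, ploidy + 1).

    A region of B dose ``d`` carries two kinds of diagnostic variants:
    those shared by the whole B complement (alternate fraction ``d/P``)
    and those specific to a single B subgenome (``min(1, d)/P`` — the
    residual 1/3-frequency sites visible inside B3:A0 regions).  With
    ``hemi_fraction`` > 0 each dose's likelihood is the corresponding
    two-component binomial mixture; this bimodal signature is what
    separates disomic from trisomic models.  A uniform outlier component
    (density 1/(depth+1)) bounds the influence of private mutations.
    """
    doses = np.arange(ploidy + 1)
    frac_shared = doses / ploidy
    frac_hemi = np.minimum(1, doses) / ploidy

    def comp(frac):
        p = (1.0 - eps) * frac + eps * (1.0 - frac)
        return binom.logpmf(alt[:, None], depth[:, None], p[None, :])

    if hemi_fraction > 0:
        ll = np.logaddexp(
            np.log1p(-hemi_fraction) + comp(frac_shared),
            np.log(hemi_fraction) + comp(frac_hemi),
        )
    else:
        ll = comp(frac_shared)
    if outlier_fraction > 0:
        out = -np.log(depth + 1.0)
        ll = np.logaddexp(
            np.log1p(-outlier_fraction) + ll,
            np.log(outlier_fraction) + out[:, None],
        )
    return ll


def window_dosage(
    alt: np.ndarray,
    depth: np.ndarray,
    ploidy: int,
    eps: float = 0.005,
    outlier_fraction: float = 0.0,
) -> tuple[int, np.ndarray]:
    """Best B dose for one window of sites, with the full log-likelihood grid.

    Returns ``(argmax dose, log-likelihood vector over doses 0..P)`` where
    each entry sums per-site binomial log-pmfs at the dose's expected
    alternate fraction.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.size == 0:
        raise ValueError("empty window")
    ll = _site_loglik(alt, depth, ploidy, eps, outlier_fraction).sum(axis=0)
    return int(np.argmax(ll)), ll


def _rolling_loglik(ll: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling sum of per-site log-likelihood rows (truncated at
    the track ends)."""
    n = ll.shape[0]
    half = window // 2
    cum = np.vstack([np.zeros((1, ll.shape[1])), np.cumsum(ll, axis=0)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return cum[hi] - cum[lo]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start_idx, end_idx inclusive, label) runs of a label vector."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i - 1, int(labels[start])))
            start = i
    return out


def segment_chromosome(
    track: pd.DataFrame,
    ploidy: int = 3,
    params: SegmentationParams | None = None,
    gene_models: pd.DataFrame | None = None,
) -> list[DosageSegment]:
    """Segment one chromosome's frequency track into dosage classes.

    ``track`` needs columns ``chrom, pos, f, depth`` (and ``gene_index``
    for gene-scale merging; without it, segment length is counted in
    sites).  Sites are classified by the dose maximising a centred
    ``window_snps``-site log-likelihood; same-dose runs become segments;
    runs spanning fewer than ``min_genes_per_segment`` genes are absorbed
    into the likelier neighbour; breakpoints are snapped to the boundary
    between the flanking genes when ``gene_models`` is given.
    """
    params = params or SegmentationParams()
    if track.empty or len(track) < params.min_snps_per_chromosome:
        chrom = str(track["chrom"].iloc[0]) if len(track) else "NA"
        start = int(track["pos"].min()) if len(track) else 1
        end = int(track["pos"].max()) if len(track) else 1
        return [
            DosageSegment(
                chromosome=chrom,
                start=start,
                end=end,
                b_dose=None,
                ploidy=ploidy,
                n_snps=len(track),
                mean_f=float(track["f"].mean()) if len(track) else float("nan"),
            )
        ]
    track = track.sort_values("pos", kind="mergesort").reset_index(drop=True)
    chrom = str(track["chrom"].iloc[0])
    depth = track["depth"].to_numpy(dtype=float)
    alt = np.rint(track["f"].to_numpy(dtype=float) * depth)

    ll = _site_loglik(
        alt, depth, ploidy, params.eps, params.outlier_fraction, params.hemi_fraction
    )
    rolled = _rolling_loglik(ll, params.window_snps)
    site_dose = np.argmax(rolled, axis=1)

    gene_idx = (
        track["gene_index"].to_numpy()
        if "gene_index" in track.columns
        else np.arange(len(track))
    )

    def run_genes(a: int, b: int) -> int:
        return len(np.unique(gene_idx[a : b + 1]))

    runs = _runs(site_dose)
    # absorb short runs (in gene span or site count) into the likelier side
    changed = True
    while changed and len(runs) > 1:
        changed = False
        spans = [run_genes(a, b) for a, b, _ in runs]
        snps = [b - a + 1 for a, b, _ in runs]
        order = int(np.argmin(spans))
        a, b, lab = runs[order]
        if (
            spans[order] < params.min_genes_per_segment
            or snps[order] < params.min_snps_per_segment
        ):
            block = ll[a : b + 1].sum(axis=0)
            left = runs[order - 1][2] if order > 0 else None
            right = runs[order + 1][2] if order < len(runs) - 1 else None
            if left is None:
                new = right
            elif right is None:
                new = left
            else:
                new = left if block[left] >= block[right] else right
            runs[order] = (a, b, new)
            merged = []
            for r in runs:
                if merged and merged[-1][2] == r[2]:
                    merged[-1] = (merged[-1][0], r[1], r[2])
                else:
                    merged.append(r)
            runs = merged
            changed = True

    # snap breakpoints to gene boundaries and tile the chromosome
    if gene_models is not None:
        gm = gene_models.loc[gene_models["chrom"] == chrom]
        gene_start = dict(zip(gm["gene_index"], gm["start"]))
        chrom_start = int(gm["start"].min())
        chrom_end = int(gm["end"].max())
    else:
        gene_start = {}
        chrom_start = int(track["pos"].iloc[0])
        chrom_end = int(track["pos"].iloc[-1])

    segments: list[DosageSegment] = []
    for i, (a, b, lab) in enumerate(runs):
        if i == 0:
            start = chrom_start
        else:
            first_gene = int(gene_idx[a])
            start = int(gene_start.get(first_gene, track["pos"].iloc[a]))
        segments.append(
            DosageSegment(
                chromosome=chrom,
                start=start,
                end=0,  # fixed below
                b_dose=int(lab),
                ploidy=ploidy,
                n_snps=b - a + 1,
                mean_f=float(track["f"].iloc[a : b + 1].mean()),
            )
        )
    for i, seg in enumerate(segments):
        seg.end = (
            chrom_end if i == len(segments) - 1 else segments[i + 1].start - 1
        )
    return segments


@dataclass
class AneuploidyCall:
    """Ploidy decision for one chromosome (and its arms)."""

    chromosome: str
    ploidy: int
    delta_loglik: float  # logL(disomic) - logL(trisomic); positive favours loss
    arm_ploidies: dict[str, int] = field(default_factory=dict)
    arm_delta_loglik: dict[str, float] = field(default_factory=dict)
    uncallable: bool = False


def _track_loglik(
    track: pd.DataFrame, ploidy: int, params: SegmentationParams
) -> float:
    """Total log-likelihood of the best segmentation at a given ploidy."""
    segments = segment_chromosome(track, ploidy, params)
    t = track.sort_values("pos", kind="mergesort").reset_index(drop=True)
    depth = t["depth"].to_numpy(dtype=float)
    alt = np.rint(t["f"].to_numpy(dtype=float) * depth)
    ll = _site_loglik(
        alt, depth, ploidy, params.eps, params.outlier_fraction, params.hemi_fraction
    )
    total = 0.0
    pos = t["pos"].to_numpy()
    for seg in segments:
        mask = (pos >= seg.start) & (pos <= seg.end)
        if seg.b_dose is None:
            continue
        total += float(ll[mask, seg.b_dose].sum())
    return total


def detect_aneuploidy(
    track: pd.DataFrame,
    params: SegmentationParams | None = None,
    centromere: int | None = None,
) -> AneuploidyCall:
    """Compare trisomic vs disomic models for a chromosome and its arms.

    Disomy is called when the best disomic segmentation beats the best
    trisomic one by at least ``disomy_delta_loglik`` nats; the comparison
    is repeated on each arm (split at ``centromere`` or, absent one, the
    midpoint of the covered interval) to catch partial losses.
    """
    params = params or SegmentationParams()
    chrom = str(track["chrom"].iloc[0]) if len(track) else "NA"
    if len(track) < params.min_snps_per_chromosome:
        return AneuploidyCall(
            chromosome=chrom, ploidy=3, delta_loglik=float("nan"), uncallable=True
        )
    ll3 = _track_loglik(track, 3, params)
    ll2 = _track_loglik(track, 2, params)
    delta = ll2 - ll3
    ploidy = 2 if delta >= params.disomy_delta_loglik else 3

    split = centromere
    if split is None:
        split = int((track["pos"].min() + track["pos"].max()) // 2)
    arms = {"p": track.loc[track["pos"] <= split], "q": track.loc[track["pos"] > split]}
    arm_p: dict[str, int] = {}
    arm_d: dict[str, float] = {}
    for name, arm in arms.items():
        if len(arm) < params.min_snps_per_chromosome:
            continue
        d = _track_loglik(arm, 2, params) - _track_loglik(arm, 3, params)
        arm_d[name] = d
        arm_p[name] = 2 if d >= params.disomy_delta_loglik else 3
    return AneuploidyCall(
        chromosome=chrom,
        ploidy=ploidy,
        delta_loglik=delta,
        arm_ploidies=arm_p,
        arm_delta_loglik=arm_d,
    )


# ----------------------------------------------------------------------
def annotate_genes(
    segments: list[DosageSegment], gene_models: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every anchored gene the dosage of the segment containing its
    midpoint.

    Returns ``(per_gene, class_counts)``; genes on the unanchored
    scaffold label are excluded with an audit tag, and class counts report
    each label's gene count and percentage of anchored genes.
    """
    seg_by_chrom: dict[str, list[DosageSegment]] = {}
    for seg in segments:
        seg_by_chrom.setdefault(seg.chromosome, []).append(seg)
    rows = []
    for row in gene_models.itertuples(index=False):
        if row.chrom == UNANCHORED:
            rows.append([row.gene_id, row.chrom, None, None, None, "unanchored"])
            continue
        mid = (row.start + row.end) // 2
        hit = None
        for seg in seg_by_chrom.get(row.chrom, []):
            if seg.start <= mid <= seg.end:
                hit = seg
                break
        if hit is None or hit.b_dose is None:
            rows.append([row.gene_id, row.chrom, None, None, None, "uncallable"])
        else:
            rows.append(
                [row.gene_id, row.chrom, hit.b_dose, hit.a_dose, hit.ploidy, hit.label]
            )
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "b_dose", "a_dose", "ploidy", "label"]
    )
    anchored = per_gene.loc[per_gene["label"] != "unanchored"]
    counts = anchored["label"].value_counts().rename_axis("label").reset_index(name="n_genes")
    counts["percent"] = (100.0 * counts["n_genes"] / len(anchored)).round(2)
    return per_gene, counts


@dataclass
class CultivarStructureReport:
    """Full genome-structure inference for one cultivar."""

    cultivar: str
    genome_group: str
    segments: list[DosageSegment]
    aneuploidy: list[AneuploidyCall]
    per_gene: pd.DataFrame
    class_counts: pd.DataFrame
    deviating_segments: list[DosageSegment]

    @property
    def baseline_label(self) -> str:
        b = baseline_b_dose(self.genome_group)
        return f"B{b}:A{3 - b}"


def structure_report(
    tracks: pd.DataFrame,
    genome_group: str,
    gene_models: pd.DataFrame,
    cultivar: str = "",
    params: SegmentationParams | None = None,
    centromeres: dict[str, int] | None = None,
) -> CultivarStructureReport:
    """Aneuploidy-aware segmentation of every anchored chromosome.

    ``tracks`` is a multi-chromosome frequency frame.  Each chromosome's
    ploidy is decided first; segmentation then runs at the called ploidy.
    Deviating segments are those whose label differs from the genome
    group's baseline (at ploidy 3).
    """
    params = params or SegmentationParams()
    baseline = f"B{baseline_b_dose(genome_group)}:A{3 - baseline_b_dose(genome_group)}"
    segments: list[DosageSegment] = []
    calls: list[AneuploidyCall] = []
    for chrom, sub in tracks.groupby("chrom", sort=True):
        if chrom == UNANCHORED:
            continue
        cen = (centromeres or {}).get(str(chrom))
        call = detect_aneuploidy(sub, params, centromere=cen)
        calls.append(call)
        segments.extend(
            segment_chromosome(sub, call.ploidy, params, gene_models=gene_models)
        )
    per_gene, counts = annotate_genes(segments, gene_models)
    # aneuploid (disomic) segments are reported via the aneuploidy calls,
    # not as dosage-deviating regions (they are masked downstream instead)
    deviating = [
        s
        for s in segments
        if s.b_dose is not None and s.ploidy == 3 and s.label != baseline
    ]
    return CultivarStructureReport(
        cultivar=cultivar,
        genome_group=genome_group,
        segments=segments,
        aneuploidy=calls,
        per_gene=per_gene,
        class_counts=counts,
        deviating_segments=deviating,
    )


def segments_to_bed(segments: list[DosageSegment]) -> pd.DataFrame:
    """Segments as a BED-style frame (0-based half-open, name=label,
    score=n_snps)."""
    return pd.DataFrame(
        {
            "chrom": [s.chromosome for s in segments],
            "start": [s.start - 1 for s in segments],
            "end": [s.end for s in segments],
            "name": [s.label for s in segments],
            "score": [s.n_snps for s in segments],
        }
    )
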