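"""Container for per-site, per-sample allelic read depths.

A :class:`SnpTable` couples a site annotation frame (chromosome, 1-based
position, containing gene, alleles) with two integer depth matrices of
identical shape, one for reads supporting the reference allele and one for
the retained alternate allele.  At most one alternate allele is kept per
site; multi-allelic records are reduced to the highest-depth alternate on
input, because the downstream frequency model is biallelic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "gene_id", "ref_allele", "alt_allele"]


@dataclass
class SnpTable:
    """Sites plus aligned ref/alt depth matrices (sites x samples)."""

    sites: pd.DataFrame
    ref_depth: pd.DataFrame
    alt_depth: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "pos"):
            if col not in self.sites.columns:
                raise ValueError(f"sites frame lacks required column {col!r}")
        if not (
            self.sites.index.equals(self.ref_depth.index)
            and self.sites.index.equals(self.alt_depth.index)
        ):
            raise ValueError("sites and depth matrices must share an index")
        if list(self.ref_depth.columns) != list(self.alt_depth.columns):
            raise ValueError("ref and alt depth matrices must share sample columns")
        if (self.ref_depth.to_numpy() < 0).any() or (self.alt_depth.to_numpy() < 0).any():
            raise ValueError("read depths must be non-negative")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    # ------------------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.ref_depth.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, mask) -> "SnpTable":
        """Row-subset by a boolean mask or index array; keeps alignment."""
        sites = self.sites.loc[mask]
        return SnpTable(
            sites=sites,
            ref_depth=self.ref_depth.loc[sites.index],
            alt_depth=self.alt_depth.loc[sites.index],
        )

    def sort(self) -> "SnpTable":
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index
        return SnpTable(
            sites=self.sites.loc[order],
            ref_depth=self.ref_depth.loc[order],
            alt_depth=self.alt_depth.loc[order],
        )

    # ------------------------------------------------------------------
    # TSV dialect: chrom pos gene_id ref_allele alt_allele ref:<s> alt:<s> ...
    def to_tsv(self, path: str | Path) -> None:
        out = self.sites.copy()
        for s in self.samples:
            out[f"ref:{s}"] = self.ref_depth[s].to_numpy()
            out[f"alt:{s}"] = self.alt_depth[s].to_numpy()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpTable":
        df = pd.read_csv(path, sep="\t")
        ref_cols = [c for c in df.columns if c.startswith("ref:")]
        alt_cols = [c for c in df.columns if c.startswith("alt:")]
        samples = [c[4:] for c in ref_cols]
        if samples != [c[4:] for c in alt_cols]:
            raise ValueError("mismatched ref:/alt: sample columns")
        site_cols = [c for c in df.columns if ":" not in c]
        ref = df[ref_cols].astype(int)
        ref.columns = samples
        alt = df[alt_cols].astype(int)
        alt.columns = samples
        return cls(sites=df[site_cols], ref_depth=ref, alt_depth=alt)

    # ------------------------------------------------------------------
    # Minimal VCF with per-sample AD (ref,alt depths).
    def to_vcf(self, path: str | Path) -> None:
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
            '"Allelic depths for the ref and alt alleles">',
        ]
        chroms = self.sites["chrom"].drop_duplicates()
        for c in chroms:
            lines.append(f"##contig=<ID={c}>")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += self.samples
        lines.append("\t".join(header))
        ref_mat = self.ref_depth.to_numpy()
        alt_mat = self.alt_depth.to_numpy()
        gene_ids = (
            self.sites["gene_id"] if "gene_id" in self.sites.columns else None
        )
        for i, (_, row) in enumerate(self.sites.iterrows()):
            site_id = str(gene_ids.iloc[i]) if gene_ids is not None else "."
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                site_id,
                str(row.get("ref_allele", "A")),
                str(row.get("alt_allele", "T")),
                ".",
                "PASS",
                ".",
                "AD",
            ]
            fields += [f"{ref_mat[i, j]},{alt_mat[i, j]}" for j in range(ref_mat.shape[1])]
            lines.append("\t".join(fields))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SnpTable":
        """Read a VCF with per-sample AD depths.

        Multi-allelic records keep the single alternate allele with the
        highest summed depth across samples.
        """
        samples: list[str] = []
        rows = []
        refs = []
        alts = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                if line.startswith("#CHROM"):
                    samples = line.split("\t")[9:]
                    continue
                parts = line.split("\t")
                chrom, pos, site_id, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
                fmt = parts[8].split(":")
                try:
                    ad_idx = fmt.index("AD")
                except ValueError:
                    raise ValueError("VCF records must carry an AD FORMAT field")
                ads = []
                for entry in parts[9:]:
                    val = entry.split(":")[ad_idx]
                    ads.append([int(x) if x != "." else 0 for x in val.split(",")])
                ad = np.asarray(ads)  # samples x (1 + n_alt)
                alt_alleles = alt.split(",")
                alt_totals = ad[:, 1:].sum(axis=0)
                best = int(np.argmax(alt_totals))
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "gene_id": None if site_id == "." else site_id,
                        "ref_allele": ref,
                        "alt_allele": alt_alleles[best],
                    }
                )
                refs.append(ad[:, 0])
                alts.append(ad[:, 1 + best])
        sites = pd.DataFrame(rows)
        ref_depth = pd.DataFrame(np.asarray(refs, dtype=int), columns=samples)
        alt_depth = pd.DataFrame(np.asarray(alts, dtype=int), columns=samples)
        return cls(sites=sites, ref_depth=ref_depth, alt_depth=alt_depth)
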