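"""Staged pipeline: simulate -> filter -> dosage -> dge -> enrich -> pie.

Each stage reads the previous stage's TSV/BED/JSON outputs from the run
directory, writes its own, and records them in a provenance manifest
(config echo, seed, package versions, per-file checksums).  A stage is
skipped on rerun when its configuration and its outputs' checksums are
unchanged; supplying a precomputed output file (e.g. a per-gene dosage
table from another tool) substitutes for the stage that would have made
it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bfilter import filter_a_polymorphic, frequency_track
from .dge import compare_cultivars, consensus_degs, rle_size_factors
from .dosage import SegmentationParams, segments_to_bed, structure_report
from .enrichment import build_enrichment_inputs, enrichment_report, hypergeom_region_test
from .layout import AneuploidyEvent, CultivarDesign, GenomeLayout, HEEvent, NoiseModel
from .pie import paralog_groups_from_mapping, pie_table, write_paralog_groups
from .simulate import simulate_cultivar_dataset
from .snptable import SnpTable

log = logging.getLogger("allohe")

STAGES = ("simulate", "filter", "dosage", "dge", "enrich", "pie")

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "stages",
    "simulate",
    "filter",
    "segmentation",
    "dge",
    "enrichment",
    "pie",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    seed: int = 0
    outdir: str = "allohe_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    dge: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    pie: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        bad = [s for s in data.get("stages", []) if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _designs_from_config(cfg: dict) -> list[CultivarDesign]:
    designs = []
    for d in cfg.get("designs", _default_designs()):
        he = [HEEvent(*ev) if isinstance(ev, (list, tuple)) else HEEvent(**ev)
              for ev in d.get("he_events", [])]
        an = [
            AneuploidyEvent(*ev) if isinstance(ev, (list, tuple)) else AneuploidyEvent(**ev)
            for ev in d.get("aneuploidy_events", [])
        ]
        designs.append(
            CultivarDesign(
                name=d["name"],
                genome_group=d["genome_group"],
                he_events=he,
                aneuploidy_events=an,
                n_replicates=d.get("n_replicates", 3),
            )
        )
    return designs


def _default_designs() -> list[dict]:
    """A compact study design: three AAA references plus one recombined ABB
    cultivar with an interstitial B1:A2 and a terminal B3:A0 exchange."""
    return [
        {"name": "auto1", "genome_group": "AAA"},
        {"name": "auto2", "genome_group": "AAA"},
        {"name": "auto3", "genome_group": "AAA"},
        {
            "name": "allo1",
            "genome_group": "ABB",
            "he_events": [
                ["chr04", 20, 39, 1],
                ["chr11", 60, 99, 3],
            ],
        },
    ]


class Pipeline:
    """Run-directory-scoped execution of the staged analysis."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}}
        self.manifest.update(
            {
                "package": "allohe",
                "version": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "seed": config.seed,
                "config": config.to_dict(),
            }
        )

    # -- provenance helpers -------------------------------------------
    def _stage_fresh(self, stage: str, cfg_hash: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or entry.get("config_hash") != cfg_hash:
            return False
        for rel, digest in entry.get("outputs", {}).items():
            p = self.outdir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def _record(self, stage: str, cfg_hash: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "config_hash": cfg_hash,
            "outputs": {
                str(p.relative_to(self.outdir)): _sha256(p) for p in outputs
            },
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    # -- stage implementations ----------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.simulate
        cfg_hash = _config_hash({"cfg": cfg, "seed": self.config.seed})
        if self._stage_fresh("simulate", cfg_hash):
            log.info("simulate: up to date, skipping")
            return
        layout = GenomeLayout(**cfg.get("layout", {}))
        noise = NoiseModel(**cfg.get("noise", {}))
        designs = _designs_from_config(cfg)
        ds = simulate_cultivar_dataset(
            designs,
            layout=layout,
            noise=noise,
            seed=self.config.seed,
            **{
                k: cfg[k]
                for k in (
                    "n_effect_genes",
                    "effect_log2fc",
                    "frac_compensated",
                    "paralog_fraction",
                )
                if k in cfg
            },
        )
        out = self.outdir
        outputs = []
        ds.gene_models.to_csv(out / "gene_models.tsv", sep="\t", index=False)
        outputs.append(out / "gene_models.tsv")
        for name, table in ds.allele_depths.items():
            p = out / f"snp_{name}.tsv"
            table.to_tsv(p)
            outputs.append(p)
        ds.counts.to_csv(out / "counts.tsv", sep="\t")
        outputs.append(out / "counts.tsv")
        ds.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
        outputs.append(out / "sample_sheet.tsv")
        ds.truth.to_json(out / "truth.json")
        outputs.append(out / "truth.json")
        by_gene = paralog_groups_from_mapping(
            ds.truth.paralog_map, ds.truth.tandem_cluster_size
        )
        write_paralog_groups(by_gene, out / "paralog_groups.tsv")
        outputs.append(out / "paralog_groups.tsv")
        self._record("simulate", cfg_hash, outputs)
        log.info("simulate: wrote %d cultivar SNP tables", len(ds.allele_depths))

    def _sheet(self) -> pd.DataFrame:
        return pd.read_csv(self.outdir / "sample_sheet.tsv", sep="\t")

    def _analyzed_cultivars(self, sheet: pd.DataFrame) -> list[str]:
        return sorted(sheet.loc[sheet["genome_group"] != "AAA", "cultivar"].unique())

    def stage_filter(self) -> None:
        cfg = self.config.filter
        cfg_hash = _config_hash(cfg)
        if self._stage_fresh("filter", cfg_hash):
            log.info("filter: up to date, skipping")
            return
        sheet = self._sheet()
        panel_cultivars = sorted(
            sheet.loc[sheet["genome_group"] == "AAA", "cultivar"].unique()
        )
        outputs = []
        for cultivar in self._analyzed_cultivars(sheet):
            table = SnpTable.from_tsv(self.outdir / f"snp_{cultivar}.tsv")
            # panel depths live in the panel cultivars' own tables; join them
            panel_tables = [
                SnpTable.from_tsv(self.outdir / f"snp_{c}.tsv") for c in panel_cultivars
            ]
            merged = SnpTable(
                sites=table.sites,
                ref_depth=pd.concat(
                    [table.ref_depth] + [t.ref_depth for t in panel_tables], axis=1
                ),
                alt_depth=pd.concat(
                    [table.alt_depth] + [t.alt_depth for t in panel_tables], axis=1
                ),
            )
            panel_samples = [
                s for t in panel_tables for s in t.samples
            ]
            res = filter_a_polymorphic(
                merged,
                panel_samples,
                min_a_depth=cfg.get("min_a_depth", 10),
                max_a_alt_fraction=cfg.get("max_a_alt_fraction", 0.05),
            )
            cultivar_samples = table.samples
            track = frequency_track(res.retained, cultivar_samples)
            p1 = self.outdir / f"audit_{cultivar}.tsv"
            res.audit.to_csv(p1, sep="\t", index=False)
            p2 = self.outdir / f"track_{cultivar}.tsv"
            track.to_csv(p2, sep="\t", index=False)
            outputs += [p1, p2]
        self._record("filter", cfg_hash, outputs)

    def stage_dosage(self) -> None:
        cfg = self.config.segmentation
        cfg_hash = _config_hash(cfg)
        if self._stage_fresh("dosage", cfg_hash):
            log.info("dosage: up to date, skipping")
            return
        pre_pg = cfg.get("precomputed_per_gene")
        sheet = self._sheet()
        outputs = []
        if pre_pg:
            # stage substitution: copy user-supplied per-gene dosage tables
            for cultivar in self._analyzed_cultivars(sheet):
                src = Path(pre_pg.format(cultivar=cultivar))
                df = pd.read_csv(src, sep="\t")
                p = self.outdir / f"per_gene_{cultivar}.tsv"
                df.to_csv(p, sep="\t", index=False)
                outputs.append(p)
            self._record("dosage", cfg_hash, outputs)
            return
        params = SegmentationParams(
            **{k: v for k, v in cfg.items() if k in SegmentationParams.__annotations__}
        )
        gene_models = pd.read_csv(self.outdir / "gene_models.tsv", sep="\t")
        for cultivar in self._analyzed_cultivars(sheet):
            track = pd.read_csv(self.outdir / f"track_{cultivar}.tsv", sep="\t")
            group = sheet.loc[sheet["cultivar"] == cultivar, "genome_group"].iloc[0]
            report = structure_report(
                track, group, gene_models, cultivar=cultivar, params=params
            )
            bed = segments_to_bed(report.segments)
            p1 = self.outdir / f"segments_{cultivar}.bed"
            bed.to_csv(p1, sep="\t", index=False, header=False)
            p2 = self.outdir / f"per_gene_{cultivar}.tsv"
            report.per_gene.to_csv(p2, sep="\t", index=False)
            aneu = pd.DataFrame(
                [
                    {
                        "chrom": c.chromosome,
                        "ploidy": c.ploidy,
                        "delta_loglik": c.delta_loglik,
                        "uncallable": c.uncallable,
                    }
                    for c in report.aneuploidy
                ]
            )
            p3 = self.outdir / f"aneuploidy_{cultivar}.tsv"
            aneu.to_csv(p3, sep="\t", index=False)
            outputs += [p1, p2, p3]
        self._record("dosage", cfg_hash, outputs)

    def stage_dge(self) -> None:
        cfg = self.config.dge
        cfg_hash = _config_hash(cfg)
        if self._stage_fresh("dge", cfg_hash):
            log.info("dge: up to date, skipping")
            return
        counts = pd.read_csv(self.outdir / "counts.tsv", sep="\t", index_col=0)
        sheet = self._sheet()
        factors = rle_size_factors(counts)
        aaa = sorted(sheet.loc[sheet["genome_group"] == "AAA", "cultivar"].unique())
        outputs = []
        for cultivar in self._analyzed_cultivars(sheet):
            results = []
            for ref in aaa:
                res = compare_cultivars(counts, sheet, cultivar, ref, size_factors=factors)
                p = self.outdir / f"de_{cultivar}_vs_{ref}.tsv"
                res.to_csv(p, sep="\t", index=False)
                outputs.append(p)
                results.append(res)
            cons = consensus_degs(
                results,
                q_threshold=cfg.get("q_threshold", 0.05),
                require_sign_concordance=cfg.get("require_sign_concordance", True),
            )
            p = self.outdir / f"consensus_{cultivar}.txt"
            p.write_text("\n".join(cons) + ("\n" if cons else ""))
            outputs.append(p)
        self._record("dge", cfg_hash, outputs)

    def stage_enrich(self) -> None:
        cfg = self.config.enrichment
        cfg_hash = _config_hash(cfg)
        if self._stage_fresh("enrich", cfg_hash):
            log.info("enrich: up to date, skipping")
            return
        sheet = self._sheet()
        outputs = []
        for cultivar in self._analyzed_cultivars(sheet):
            per_gene = pd.read_csv(self.outdir / f"per_gene_{cultivar}.tsv", sep="\t")
            degs = _read_gene_list(self.outdir / f"consensus_{cultivar}.txt")
            group = sheet.loc[sheet["cultivar"] == cultivar, "genome_group"].iloc[0]
            masked: set[str] = set()
            aneu_path = self.outdir / f"aneuploidy_{cultivar}.tsv"
            if aneu_path.exists():
                aneu = pd.read_csv(aneu_path, sep="\t")
                masked = set(aneu.loc[aneu["ploidy"] == 2, "chrom"])
            inputs = build_enrichment_inputs(
                per_gene,
                degs,
                group,
                genotype=cultivar,
                masked_chromosomes=masked,
                population=cfg.get("population", "assigned"),
            )
            report = enrichment_report([hypergeom_region_test(i) for i in inputs])
            p = self.outdir / f"enrichment_{cultivar}.tsv"
            report.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        self._record("enrich", cfg_hash, outputs)

    def stage_pie(self) -> None:
        cfg = self.config.pie
        cfg_hash = _config_hash(cfg)
        if self._stage_fresh("pie", cfg_hash):
            log.info("pie: up to date, skipping")
            return
        from .pie import load_paralog_groups

        counts = pd.read_csv(self.outdir / "counts.tsv", sep="\t", index_col=0)
        sheet = self._sheet()
        factors = rle_size_factors(counts)
        by_gene = load_paralog_groups(self.outdir / "paralog_groups.tsv", "musa")
        aaa = sorted(sheet.loc[sheet["genome_group"] == "AAA", "cultivar"].unique())
        outputs = []
        for cultivar in self._analyzed_cultivars(sheet):
            degs = _read_gene_list(self.outdir / f"consensus_{cultivar}.txt")
            # focal stats from the first AAA comparison (signs agree by construction)
            focal = pd.read_csv(
                self.outdir / f"de_{cultivar}_vs_{aaa[0]}.tsv", sep="\t"
            )
            focal = focal.loc[focal["gene_id"].isin(degs)]
            ga = sheet.loc[sheet["cultivar"] == cultivar, "sample"].tolist()
            gb = sheet.loc[sheet["cultivar"].isin(aaa), "sample"].tolist()
            table = pie_table(
                degs,
                by_gene,
                counts,
                factors,
                ga,
                gb,
                focal_results=focal,
                alpha=cfg.get("alpha", 0.05),
                max_cluster=cfg.get("max_cluster", 10),
            )
            p = self.outdir / f"pie_{cultivar}.tsv"
            table.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        self._record("pie", cfg_hash, outputs)

    # ------------------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> Path:
        todo = stages or self.config.stages
        for stage in STAGES:
            if stage not in todo:
                continue
            log.info("stage %s", stage)
            getattr(self, f"stage_{stage}")()
        return self.manifest_path


def _read_gene_list(path: Path) -> list[str]:
    text = path.read_text().strip()
    return text.splitlines() if text else []


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the configured stages; returns the manifest path."""
    return Pipeline(config).run(stages)
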