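"""End-to-end orchestration: annotation -> counting -> DE -> split -> features -> ORA.

The pipeline exchanges only TSV/JSON between stages and records a manifest
(config hash, per-stage row counts) so a rerun with the same config and seed
is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotation as ann
from . import counting as cnt
from .diffexp import NegativeBinomialDE, DEResults
from .delta import ExonIntronSplit
from .features import compare_utr_distributions
from .enrichment import hypergeom_enrich, read_gmt

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    gtf: str
    sample_sheet: str  # TSV: sample_id, condition, path
    outdir: str
    canonical_map: str | None = None
    gmt: str | None = None
    input_format: str = "placements"  # placements | sam
    fdr_cutoff: float = 0.05
    lfc_cutoff: float = 0.58
    go_adj_p: float = 0.01
    top_k: int = 10_000
    deg_rule: str = "union"
    pseudocount: float = 0.5
    prior_df: float = 20.0
    mapq_min: int = 255
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fdr_cutoff <= 1) or not (0 < self.go_adj_p <= 1):
            raise ConfigError("fdr_cutoff and go_adj_p must be in (0, 1]")
        if self.lfc_cutoff < 0 or self.top_k < 1:
            raise ConfigError("lfc_cutoff must be >= 0 and top_k >= 1")
        if self.input_format not in ("placements", "sam"):
            raise ConfigError(f"unknown input_format {self.input_format!r}")
        for label, path in [("gtf", self.gtf), ("sample_sheet", self.sample_sheet),
                            ("canonical_map", self.canonical_map), ("gmt", self.gmt)]:
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{label} path does not exist: {path}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _load_reads(sheet: pd.DataFrame, config: RunConfig) -> list[cnt.ReadAlignment]:
    """SAM files are per sample; placement TSVs may pool several samples."""
    reads: list[cnt.ReadAlignment] = []
    if config.input_format == "sam":
        for row in sheet.itertuples(index=False):
            reads.extend(cnt.read_sam(row.path, row.sample_id, mapq_min=config.mapq_min))
        return reads
    known = set(sheet["sample_id"])
    for path in dict.fromkeys(sheet["path"]):
        batch = cnt.read_placements(path)
        strays = {r.sample for r in batch} - known
        if strays:
            raise ValueError(
                f"placement file {path}: samples absent from sheet: {sorted(strays)}"
            )
        reads.extend(batch)
    return reads


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.hash(), "stages": {}}

    # --- stage 1: annotation ------------------------------------------------
    stage = "make-annotation"
    try:
        genes = ann.parse_gtf(config.gtf)
        exon_rs = [ann.constitutive_exons(g) for g in genes]
        intron_rs = [ann.constitutive_introns(g) for g in genes]
        exon_rs_nonempty = [r for r in exon_rs if r.intervals]
        intron_rs_nonempty = [r for r in intron_rs if r.intervals]
        ann.write_region_annotation(exon_rs_nonempty, outdir / "regions_exon.saf.tsv")
        ann.write_region_annotation(intron_rs_nonempty, outdir / "regions_intron.saf.tsv")
        canonical = (
            ann.read_canonical_map(config.canonical_map) if config.canonical_map else None
        )
        intron_bp = {r.gene_id: r.total_length for r in intron_rs}
        feats = ann.utr_table(genes, canonical, intron_lengths=intron_bp)
        feats.to_csv(outdir / "gene_features.tsv", sep="\t")
        manifest["stages"][stage] = {
            "genes": len(genes),
            "exon_regions": sum(len(r) for r in exon_rs),
            "intron_regions": sum(len(r) for r in intron_rs),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # --- stage 2: counting --------------------------------------------------
    stage = "count"
    try:
        sheet = cnt.read_sample_sheet(config.sample_sheet)
        condition = dict(zip(sheet["sample_id"], sheet["condition"]))
        reads = _load_reads(sheet, config)
        matrices: dict[str, cnt.CountMatrix] = {}
        for level, regionsets in (("exon", exon_rs_nonempty), ("intron", intron_rs_nonempty)):
            cm, stats = cnt.count_level(
                reads, regionsets, level,
                samples=list(sheet["sample_id"]), condition=condition,
            )
            matrices[level] = cm
            cnt.write_counts(cm, outdir / f"counts_{level}.tsv")
            manifest["stages"].setdefault(stage, {})[level] = {
                s: vars(st) for s, st in stats.items()
            }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    return _run_from_counts(matrices["exon"], matrices["intron"], feats, config,
                            outdir, manifest)


def run_from_counts(
    exon_counts: cnt.CountMatrix,
    intron_counts: cnt.CountMatrix,
    features: pd.DataFrame,
    config: RunConfig,
    genesets: dict | None = None,
) -> dict:
    """Run the statistical stages on precomputed count matrices."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.hash(), "stages": {}}
    return _run_from_counts(exon_counts, intron_counts, features, config, outdir,
                            manifest, genesets=genesets)


def _run_from_counts(cm_exon, cm_intron, feats, config, outdir, manifest, genesets=None):
    # --- stage 3: differential expression (x2 levels) -----------------------
    stage = "diffexp"
    results: dict[str, DEResults] = {}
    try:
        for cm in (cm_exon, cm_intron):
            model = NegativeBinomialDE.from_count_matrix(
                cm,
                pseudocount=config.pseudocount,
                prior_df=config.prior_df,
                fdr_cutoff=config.fdr_cutoff,
                lfc_cutoff=config.lfc_cutoff,
            )
            res = model.fit()
            results[cm.level] = res
            res.to_tsv(outdir / f"diffexp_{cm.level}.tsv")
            manifest["stages"].setdefault(stage, {})[cm.level] = {
                "tested": len(res.table),
                "degs": int(res.table["is_deg"].sum()),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 4: split analysis -------------------------------------------
    stage = "delta"
    try:
        split = ExonIntronSplit(results["exon"], results["intron"], config.deg_rule).fit()
        split.pairs.to_csv(outdir / "delta_pairs.tsv", sep="\t", float_format="%.10g")
        with open(outdir / "delta_summary.json", "w") as fh:
            json.dump(split.to_summary_dict(), fh, indent=2, sort_keys=True)
        manifest["stages"][stage] = {
            "pairs": len(split.pairs),
            "r_squared": round(split.r_squared, 6),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 5: UTR feature statistics -------------------------------------
    stage = "utr-stats"
    try:
        tables = []
        for level in ("exon", "intron"):
            res = results[level]
            background = res.top_by_basemean(config.top_k)
            deg_sets = {
                (level, "up"): res.degs("up"),
                (level, "down"): res.degs("down"),
            }
            tables.append(
                compare_utr_distributions(deg_sets, feats, background,
                                          feature_cols=("utr3", "utr5", "total_intron_bp"))
            )
        utr_cmp = pd.concat(tables, ignore_index=True)
        utr_cmp.to_csv(outdir / "utr_comparisons.tsv", sep="\t", index=False,
                       float_format="%.10g")
        manifest["stages"][stage] = {"comparisons": len(utr_cmp)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- stage 6: enrichment -------------------------------------------------
    stage = "enrich"
    try:
        if genesets is None and config.gmt:
            genesets = read_gmt(config.gmt)
        if genesets:
            study_sets = {
                "intron_up": set(results["intron"].degs("up")),
                "intron_down": set(results["intron"].degs("down")),
                "exon_up": set(results["exon"].degs("up")),
                "exon_down": set(results["exon"].degs("down")),
                "post_tx_suppressed": set(split.genes("post_tx_suppressed")),
            }
            rows = []
            for name, study in study_sets.items():
                level = "exon" if name.startswith("exon") else "intron"
                universe = set(results[level].top_by_basemean(config.top_k))
                tab = hypergeom_enrich(study & universe, genesets, universe,
                                       adj_p_cutoff=config.go_adj_p)
                tab.insert(0, "study", name)
                rows.append(tab)
            enr = pd.concat(rows, ignore_index=True)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.10g")
            manifest["stages"][stage] = {
                "tests": len(enr),
                "significant": int(enr["significant"].sum()) if len(enr) else 0,
            }
        else:
            manifest["stages"][stage] = {"tests": 0, "significant": 0}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
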