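"""Validation experiments exercising the pipeline end to end.

Each function sets up a seeded scenario, runs the package's own code path,
and returns the measured quantities as a flat dict.  The experiments double
as the acceptance workload (``scripts/acceptance.py``) and as the heavy end
of the test suite; problem sizes are chosen so the full battery runs in a
few minutes on one CPU.
"""

from __future__ import annotations

import filecmp
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel, constitutive_exons, constitutive_introns
from .counting import count_level
from .delta import ExonIntronSplit
from .diffexp import NegativeBinomialDE, bh_adjust, size_factors
from .enrichment import hypergeom_enrich
from .features import ks_two_sample
from .simulate import (
    SimConfig,
    simulate_annotation,
    simulate_counts,
    simulate_genesets,
    simulate_reads,
    simulate_truth,
)


# ---------------------------------------------------------------------------
# interval algebra vs a per-base brute force


def random_gene(rng: np.random.Generator, span_max: int = 10_000, max_isoforms: int = 5) -> GeneModel:
    """A random small gene: each isoform is an independent set of exon blocks."""
    gene_id = f"R{rng.integers(1e9):09d}"
    strand = "+" if rng.random() < 0.5 else "-"
    n_iso = int(rng.integers(1, max_isoforms + 1))
    transcripts = []
    for k in range(n_iso):
        n_ex = int(rng.integers(1, 7))
        # draw disjoint sorted blocks within the span
        cuts = np.sort(rng.choice(span_max, size=2 * n_ex, replace=False))
        exons = [(int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(n_ex)]
        exons = [(s, e) for s, e in exons if s < e]
        if not exons:
            exons = [(0, int(rng.integers(1, span_max)))]
        transcripts.append(
            TranscriptModel(f"{gene_id}.T{k + 1}", gene_id, "ensembl", "chrS", strand, exons)
        )
    return GeneModel(gene_id, gene_id, transcripts)


def brute_force_regions(gene: GeneModel, span_max: int = 10_000):
    """Per-base membership oracle for constitutive exons and introns."""
    span = gene.span
    n_tx = len(gene.transcripts)
    cover = np.zeros(span_max, dtype=np.int32)
    for tx in gene.transcripts:
        mask = np.zeros(span_max, dtype=bool)
        for s, e in tx.exons:
            mask[s:e] = True
        cover += mask
    exonic_all = cover == n_tx
    exonic_none = cover == 0
    in_span = np.zeros(span_max, dtype=bool)
    in_span[span.start:span.end] = True

    def runs(mask):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1
        return list(zip(starts.tolist(), ends.tolist()))

    return runs(exonic_all & in_span), runs(exonic_none & in_span)


def interval_algebra_oracle(seed: int, n_genes: int = 500) -> dict:
    """Compare constitutive region derivation with the per-base oracle."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_genes):
        gene = random_gene(rng)
        exp_ex, exp_in = brute_force_regions(gene)
        if constitutive_exons(gene).intervals != exp_ex:
            mismatches += 1
        elif constitutive_introns(gene).intervals != exp_in:
            mismatches += 1
    return {"mismatches": mismatches, "n": n_genes}


# ---------------------------------------------------------------------------
# read counting: conservation and truth recovery


def counting_truth(seed: int, n_genes: int = 200) -> dict:
    """Simulate read placements and check counting reproduces the bookkeeping."""
    config = SimConfig(
        n_genes=n_genes,
        baseline_meanlog=float(np.log(0.02)),
        seed=seed,
    )
    ann = simulate_annotation(config, seed)
    reads, cm_exon_truth, cm_intron_truth = simulate_reads(ann, seed)
    exon_rs = [constitutive_exons(g) for g in ann.genes]
    intron_rs = [constitutive_introns(g) for g in ann.genes]
    samples = cm_exon_truth.sample_ids
    total_reads = len(reads)

    violations = 0
    mismatch_cells = 0
    for regionsets, truth_cm in ((exon_rs, cm_exon_truth), (intron_rs, cm_intron_truth)):
        level_reads = [r for r in reads if r.read_id.startswith(f"r_{truth_cm.level}_")]
        cm, stats = count_level(level_reads, regionsets, truth_cm.level, samples=samples,
                                condition=truth_cm.condition)
        per_sample_totals = {s: 0 for s in samples}
        for r in level_reads:
            per_sample_totals[r.sample] += 1
        for s in samples:
            if stats[s].total != per_sample_totals[s]:
                violations += 1
        mismatch_cells += int(
            (cm.counts.reindex(index=truth_cm.counts.index).fillna(0).astype(int)
             != truth_cm.counts).to_numpy().sum()
        )
    return {
        "conservation_violations": violations,
        "count_mismatch_cells": mismatch_cells,
        "n": total_reads,
    }


# ---------------------------------------------------------------------------
# closed-form statistics


def closed_forms() -> dict:
    """Textbook instances with exact answers, computed by the package."""
    bh = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    bh_err = float(np.max(np.abs(bh - 0.04)))

    ks = ks_two_sample([1.0, 3.0], [2.0, 4.0])

    hg = hypergeom_enrich(
        {"g1", "g2", "g3", "g4"},
        {"S": ("set", [f"g{i}" for i in range(1, 6)])},
        {f"g{i}" for i in range(1, 11)},
    )
    hg_p = float(hg["pvalue"].iloc[0])

    counts = pd.DataFrame({"s1": [10, 20, 40, 5], "s2": [20, 40, 80, 10]})
    sf = size_factors(counts)
    sf_err = float(max(abs(sf["s1"] - 1 / math.sqrt(2)), abs(sf["s2"] - math.sqrt(2))))

    return {
        "bh_adjusted_error": bh_err,
        "ks_d": ks.d_statistic,
        "hypergeom_p": hg_p,
        "hypergeom_p_error": abs(hg_p - 5.0 / 210.0),
        "size_factor_error": sf_err,
        "n": 4,
    }


# ---------------------------------------------------------------------------
# null calibration


def null_calibration(seed: int, n_genes: int = 2000) -> dict:
    """All-null simulation at NB dispersion 0.05: type-I error and BH DEGs."""
    config = SimConfig(
        n_genes=n_genes,
        fraction_up=0.0,
        fraction_down=0.0,
        fraction_post_tx_suppressed=0.0,
        dispersion=0.05,
        seed=seed,
    )
    truth = simulate_truth(config, seed)
    cm_exon, _, _ = simulate_counts(truth, seed)
    res = NegativeBinomialDE.from_count_matrix(cm_exon).fit()
    p = res.table["pvalue"].dropna()
    return {
        "frac_p_lt_05": float((p < 0.05).mean()),
        "frac_bh_deg": float(res.table["is_deg"].mean()),
        "n": int(len(p)),
    }


# ---------------------------------------------------------------------------
# effect recovery


def effect_recovery(seed: int, n_genes: int = 2000) -> dict:
    """Genes with true transcriptional effect +1.5 and no post-tx effect."""
    config = SimConfig(
        n_genes=n_genes,
        effect_low=1.5,
        effect_high=1.5,
        fraction_post_tx_suppressed=0.0,
        dispersion=0.05,
        seed=seed,
    )
    truth = simulate_truth(config, seed)
    cm_exon, cm_intron, _ = simulate_counts(truth, seed)
    res_ex = NegativeBinomialDE.from_count_matrix(cm_exon).fit()
    res_in = NegativeBinomialDE.from_count_matrix(cm_intron).fit()
    up = truth.table.index[truth.table["group"] == "up"]
    out = {}
    for label, res in (("exon", res_ex), ("intron", res_in)):
        tab = res.table.reindex(up).dropna()
        tab = tab[tab["baseMean"] >= 100]
        out[f"mean_err_{label}"] = float((tab["log2FC"] - 1.5).mean())
        out[f"n_{label}"] = int(len(tab))
    out["n"] = min(out.pop("n_exon"), out.pop("n_intron"))
    return out


# ---------------------------------------------------------------------------
# R^2 separation


def _fit_split(config: SimConfig, seed: int) -> float:
    truth = simulate_truth(config, seed)
    cm_exon, cm_intron, _ = simulate_counts(truth, seed)
    split = ExonIntronSplit(
        NegativeBinomialDE.from_count_matrix(cm_exon).fit(),
        NegativeBinomialDE.from_count_matrix(cm_intron).fit(),
    ).fit()
    return split.r_squared


def r2_separation(seed: int, n_genes: int = 2000) -> dict:
    """Default simulation without vs with post-transcriptional suppression.

    The suppressed scenario converts 30% of the up-regulated genes into
    decay targets (transcriptionally up, mature mRNA flat).
    """
    base = SimConfig(n_genes=n_genes, seed=seed)
    cfg_none = replace(base, fraction_post_tx_suppressed=0.0)
    f_total = base.fraction_up + base.fraction_post_tx_suppressed
    cfg_sup = replace(
        base,
        fraction_up=0.7 * f_total,
        fraction_post_tx_suppressed=0.3 * f_total,
    )
    r2_none = _fit_split(cfg_none, seed)
    r2_sup = _fit_split(cfg_sup, seed)
    return {
        "r2_no_posttx": r2_none,
        "r2_with_posttx": r2_sup,
        "r2_drop": r2_none - r2_sup,
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# UTR/KS replicates


def utr_ks_replicates(seed: int, n_reps: int = 100, n_genes: int = 2000) -> dict:
    """Across seeded replicates: does the intron-up DEG set -- and not the
    exon-down set -- show a 3' UTR length shift against the background?"""
    sig_intron_up = 0
    sig_exon_down = 0
    n_exon_down_tests = 0
    for i in range(n_reps):
        rep_seed = seed * 100_000 + i
        config = SimConfig(n_genes=n_genes, seed=rep_seed)
        truth = simulate_truth(config, rep_seed)
        cm_exon, cm_intron, _ = simulate_counts(truth, rep_seed)
        res_ex = NegativeBinomialDE.from_count_matrix(cm_exon).fit()
        res_in = NegativeBinomialDE.from_count_matrix(cm_intron).fit()
        utr3 = truth.table["utr3"].astype(float)

        bg_in = res_in.top_by_basemean(10_000)
        deg_in_up = [g for g in res_in.degs("up") if g in utr3.index]
        if deg_in_up:
            ks = ks_two_sample(utr3.loc[deg_in_up], utr3.loc[bg_in])
            if ks.pvalue < 0.01:
                sig_intron_up += 1
        bg_ex = res_ex.top_by_basemean(10_000)
        deg_ex_down = [g for g in res_ex.degs("down") if g in utr3.index]
        if deg_ex_down:
            n_exon_down_tests += 1
            ks = ks_two_sample(utr3.loc[deg_ex_down], utr3.loc[bg_ex])
            if ks.pvalue < 0.01:
                sig_exon_down += 1
    return {
        "frac_sig_intron_up": sig_intron_up / n_reps,
        "frac_sig_exon_down": sig_exon_down / max(n_exon_down_tests, 1),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# planted-set enrichment


def planted_enrichment(seed: int, n_genes: int = 2000) -> dict:
    """Is the planted decay-target set the top hit for post_tx_suppressed?"""
    config = SimConfig(n_genes=n_genes, seed=seed)
    truth = simulate_truth(config, seed)
    genesets = simulate_genesets(truth, seed + 7)
    cm_exon, cm_intron, _ = simulate_counts(truth, seed)
    res_ex = NegativeBinomialDE.from_count_matrix(cm_exon).fit()
    res_in = NegativeBinomialDE.from_count_matrix(cm_intron).fit()
    split = ExonIntronSplit(res_ex, res_in).fit()
    universe = set(res_ex.top_by_basemean(10_000)) & set(res_in.table.index)
    study = set(split.genes("post_tx_suppressed")) & universe
    table = hypergeom_enrich(study, genesets, universe)
    top = table.iloc[0]
    return {
        "planted_is_top_hit": int(top["set_id"] == config.planted_set_name),
        "planted_adj_p": float(
            table.set_index("set_id")["adj_pvalue"].get(config.planted_set_name, 1.0)
        ),
        "n_study": len(study),
        "n": len(table),
    }


# ---------------------------------------------------------------------------
# determinism


def determinism(seed: int, workdir: str | Path, n_genes: int = 60) -> dict:
    """Run the full pipeline twice with one config+seed; outputs must be
    byte-identical."""
    from . import annotation as ann_io
    from .counting import write_placements
    from .enrichment import write_gmt
    from .pipeline import RunConfig, run_all

    workdir = Path(workdir)
    indir = workdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    config = SimConfig(n_genes=n_genes, baseline_meanlog=float(np.log(0.02)), seed=seed)
    ann = simulate_annotation(config, seed)
    reads, cm_exon, _ = simulate_reads(ann, seed)
    (indir / "annotation.gtf").write_text(ann.gtf_text)
    ann_io.write_canonical_map(ann.canonical, indir / "canonical.tsv")
    write_gmt(ann.genesets, indir / "genesets.gmt")
    write_placements(reads, indir / "placements.tsv")
    sheet = pd.DataFrame(
        {
            "sample_id": cm_exon.sample_ids,
            "condition": [cm_exon.condition[s] for s in cm_exon.sample_ids],
            "path": [str(indir / "placements.tsv")] * len(cm_exon.sample_ids),
        }
    )
    sheet.to_csv(indir / "samples.tsv", sep="\t", index=False)

    outputs = []
    for run in ("run1", "run2"):
        run_config = RunConfig(
            gtf=str(indir / "annotation.gtf"),
            sample_sheet=str(indir / "samples.tsv"),
            canonical_map=str(indir / "canonical.tsv"),
            gmt=str(indir / "genesets.gmt"),
            outdir=str(workdir / run),
            seed=seed,
        )
        # the manifest embeds outdir via the config, so compare tables only
        run_all(run_config)
        outputs.append(workdir / run)

    files = sorted(
        p.name for p in outputs[0].iterdir() if p.suffix in (".tsv", ".json")
        and p.name != "manifest.json"
    )
    identical = all(
        filecmp.cmp(outputs[0] / name, outputs[1] / name, shallow=False) for name in files
    )
    return {"identical": int(identical), "n": len(files)}
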