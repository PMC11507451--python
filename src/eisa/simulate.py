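"""Synthetic two-condition RNA-seq with independently movable pre-mRNA and mRNA.

The generator emulates the study design the pipeline targets: liver RNA-seq
with three control and three treated replicates, where each gene has a
transcriptional log2 effect Δt (moving pre-mRNA, hence intron counts) and a
post-transcriptional log2 effect Δp (moving mature mRNA on top of
transcription), so that

    expected intron log2FC = Δt
    expected exon   log2FC = Δt + Δp.

A designated "decay target" subset is transcriptionally up- and
post-transcriptionally down-regulated (Δt = +1.5, Δp = -1.5 by default) and
carries a 3' UTR three times the background length — the footprint of
NMD-mediated suppression the downstream feature statistics should recover.

Counts are negative-binomial (variance mu + alpha mu^2) around means
proportional to per-gene concentration x region length x per-sample library
factor.  Everything is driven by one seeded generator: identical seeds give
byte-identical annotations, counts and read placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel, constitutive_exons, constitutive_introns
from .counting import CountMatrix, ReadAlignment


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions emulated."""

    n_genes: int = 2000
    n_per_condition: int = 3  # replicates per diet group
    max_isoforms: int = 3
    n_exons_range: tuple[int, int] = (3, 8)
    exon_len_meanlog: float = float(np.log(180.0))
    exon_len_sdlog: float = 0.5
    intron_len_meanlog: float = float(np.log(800.0))
    intron_len_sdlog: float = 0.7
    baseline_meanlog: float = float(np.log(0.5))  # per-bp exon read density
    baseline_sdlog: float = 1.0
    intron_density: float = 0.2  # pre-mRNA read density relative to mRNA
    dispersion: float = 0.03
    libsize_sdlog: float = 0.08
    fraction_up: float = 0.10
    fraction_down: float = 0.10
    fraction_post_tx_suppressed: float = 0.05
    effect_low: float = 0.75
    effect_high: float = 1.7
    decay_delta_t: float = 1.5
    decay_delta_p: float = -1.5
    utr3_base: float = 400.0
    utr3_sdlog: float = 0.6
    utr3_multiplier: float = 3.0
    utr5_base: float = 150.0
    utr5_sdlog: float = 0.6
    utr5_multiplier: float = 2.0
    min_cds: int = 300
    n_random_sets: int = 20
    random_set_size_range: tuple[int, int] = (20, 100)
    planted_set_name: str = "PLANTED_DECAY"
    read_length: int = 75
    genes_per_chrom: int = 200
    intergenic_gap: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        total = self.fraction_up + self.fraction_down + self.fraction_post_tx_suppressed
        if total > 1.0 + 1e-12:
            raise ValueError(f"effect fractions sum to {total:.3f} > 1")
        if self.n_genes < 1 or self.n_per_condition < 2:
            raise ValueError("need n_genes >= 1 and n_per_condition >= 2")
        if self.n_exons_range[0] < 2:
            raise ValueError("genes need >= 2 exons to own a constitutive intron")
        if min(self.utr3_base, self.utr5_base, self.intron_density) <= 0:
            raise ValueError("lengths and densities must be positive")


@dataclass
class SimTruth:
    """Ground truth: per-gene effects/features plus the isoform structure."""

    table: pd.DataFrame  # indexed by gene_id
    structure: list[dict]  # exon_lens, intron_lens, skipped (per extra isoform)
    config: SimConfig

    def sample_names(self) -> tuple[list[str], list[str]]:
        n = self.config.n_per_condition
        return (
            [f"ctrl_{i + 1}" for i in range(n)],
            [f"hfd_{i + 1}" for i in range(n)],
        )

    def condition_map(self) -> dict[str, str]:
        ctrl, trt = self.sample_names()
        return {**{s: "control" for s in ctrl}, **{s: "treated" for s in trt}}


@dataclass
class SimAnnotation:
    gtf_text: str
    genes: list[GeneModel]
    canonical: dict[str, str]
    genesets: dict[str, tuple[str, list[str]]]
    truth: SimTruth


def _lognormal_int(rng, meanlog, sdlog, size, lo, hi):
    vals = np.exp(rng.normal(meanlog, sdlog, size=size))
    return np.clip(np.round(vals).astype(int), lo, hi)


def simulate_truth(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Draw gene structures, regulatory effects and UTR features."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    n = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]

    # regulatory groups
    n_pt = round(config.fraction_post_tx_suppressed * n)
    n_up = round(config.fraction_up * n)
    n_down = round(config.fraction_down * n)
    order = rng.permutation(n)
    group = np.full(n, "null", dtype=object)
    group[order[:n_pt]] = "decay_target"
    group[order[n_pt:n_pt + n_up]] = "up"
    group[order[n_pt + n_up:n_pt + n_up + n_down]] = "down"

    delta_t = np.zeros(n)
    delta_p = np.zeros(n)
    mag = rng.uniform(config.effect_low, config.effect_high, size=n)
    delta_t[group == "up"] = mag[group == "up"]
    delta_t[group == "down"] = -mag[group == "down"]
    delta_t[group == "decay_target"] = config.decay_delta_t
    delta_p[group == "decay_target"] = config.decay_delta_p

    # UTR features: decay targets sit at base * multiplier, others log-normal
    utr3 = np.round(config.utr3_base * np.exp(rng.normal(0, config.utr3_sdlog, n))).astype(int)
    utr5 = np.round(config.utr5_base * np.exp(rng.normal(0, config.utr5_sdlog, n))).astype(int)
    is_decay = group == "decay_target"
    utr3[is_decay] = int(round(config.utr3_base * config.utr3_multiplier))
    utr5[is_decay] = int(round(config.utr5_base * config.utr5_multiplier))
    utr3 = np.clip(utr3, 10, None)
    utr5 = np.clip(utr5, 10, None)

    structure: list[dict] = []
    exon_bp = np.zeros(n, dtype=int)  # constitutive-exon bp
    full_exon_bp = np.zeros(n, dtype=int)
    intron_bp = np.zeros(n, dtype=int)
    lo_e, hi_e = config.n_exons_range
    for i in range(n):
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        exon_lens = _lognormal_int(rng, config.exon_len_meanlog, config.exon_len_sdlog,
                                   n_ex, 50, 4000)
        intron_lens = _lognormal_int(rng, config.intron_len_meanlog, config.intron_len_sdlog,
                                     n_ex - 1, 100, 20000)
        # grow terminal exons so the canonical transcript fits UTRs + a CDS
        deficit = int(utr5[i] + utr3[i] + config.min_cds - exon_lens.sum())
        if deficit > 0:
            exon_lens[0] += deficit - deficit // 2
            exon_lens[-1] += deficit // 2
        n_iso = int(rng.integers(1, config.max_isoforms + 1))
        skipped: list[int] = []
        for _ in range(n_iso - 1):
            if n_ex >= 3:
                skipped.append(int(rng.integers(1, n_ex - 1)))
            else:
                skipped.append(-1)  # duplicate of the full isoform
        const_mask = np.ones(n_ex, dtype=bool)
        for s in skipped:
            if s >= 0:
                const_mask[s] = False
        structure.append(
            {"exon_lens": exon_lens, "intron_lens": intron_lens, "skipped": skipped}
        )
        exon_bp[i] = int(exon_lens[const_mask].sum())
        full_exon_bp[i] = int(exon_lens.sum())
        intron_bp[i] = int(intron_lens.sum())

    baseline = np.exp(rng.normal(config.baseline_meanlog, config.baseline_sdlog, n))
    strand = rng.choice(["+", "-"], size=n)

    table = pd.DataFrame(
        {
            "group": group,
            "delta_t": delta_t,
            "delta_p": delta_p,
            "is_decay_target": is_decay,
            "utr5": utr5,
            "utr3": utr3,
            "exon_bp": exon_bp,
            "full_exon_bp": full_exon_bp,
            "intron_bp": intron_bp,
            "baseline": baseline,
            "strand": strand,
            "exon_mu0": baseline * exon_bp,
            "intron_mu0": baseline * intron_bp * config.intron_density,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimTruth(table=table, structure=structure, config=config)


# ---------------------------------------------------------------------------
# Annotation emission


def _cds_blocks(exons: list[tuple[int, int]], left_clip: int, right_clip: int):
    """Exonic bases after removing clips from the genomic left/right ends."""
    total = sum(e - s for s, e in exons)
    lo, hi = left_clip, total - right_clip
    out = []
    offset = 0
    for s, e in exons:
        length = e - s
        a, b = max(lo, offset), min(hi, offset + length)
        if a < b:
            out.append((s + (a - offset), s + (b - offset)))
        offset += length
    return out


def simulate_annotation(config: SimConfig, seed: int | None = None) -> SimAnnotation:
    """Materialise the truth as GTF text, gene models, canonical map and GMT."""
    truth = simulate_truth(config, seed)
    rng = np.random.default_rng((seed if seed is not None else config.seed) + 1_000_003)
    genes: list[GeneModel] = []
    gtf_lines: list[str] = []
    canonical: dict[str, str] = {}
    cursors: dict[str, int] = {}

    for i, gene_id in enumerate(truth.table.index):
        row = truth.table.iloc[i]
        st = truth.structure[i]
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        start = cursors.get(chrom, 1000)
        exon_lens, intron_lens = st["exon_lens"], st["intron_lens"]
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        cursors[chrom] = pos + config.intergenic_gap
        strand = row["strand"]

        tx_full_id = f"{gene_id}.T1"
        canonical[gene_id] = tx_full_id
        left_clip = int(row["utr5"] if strand == "+" else row["utr3"])
        right_clip = int(row["utr3"] if strand == "+" else row["utr5"])
        cds = _cds_blocks(exons, left_clip, right_clip)

        transcripts = [
            TranscriptModel(tx_full_id, gene_id, "ensembl", chrom, strand,
                            exons=list(exons), cds=cds)
        ]
        for k, skip in enumerate(st["skipped"], start=2):
            iso_exons = [e for j, e in enumerate(exons) if j != skip]
            transcripts.append(
                TranscriptModel(f"{gene_id}.T{k}", gene_id, "ensembl", chrom, strand,
                                exons=iso_exons)
            )
        gene = GeneModel(gene_id=gene_id, gene_name=gene_id, transcripts=transcripts)
        genes.append(gene)

        span = gene.span
        attrs_g = f'gene_id "{gene_id}"; gene_name "{gene_id}";'
        gtf_lines.append(
            f"{chrom}\tensembl\tgene\t{span.start + 1}\t{span.end}\t.\t{strand}\t.\t{attrs_g}"
        )
        for tx in transcripts:
            attrs_t = f'gene_id "{gene_id}"; transcript_id "{tx.transcript_id}"; gene_name "{gene_id}";'
            gtf_lines.append(
                f"{chrom}\tensembl\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t{strand}\t.\t{attrs_t}"
            )
            for s, e in tx.exons:
                gtf_lines.append(
                    f"{chrom}\tensembl\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs_t}"
                )
            for s, e in tx.cds or []:
                gtf_lines.append(
                    f"{chrom}\tensembl\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t{attrs_t}"
                )

    genesets = simulate_genesets(truth, rng)

    return SimAnnotation(
        gtf_text="\n".join(gtf_lines) + "\n",
        genes=genes,
        canonical=canonical,
        genesets=genesets,
        truth=truth,
    )


def simulate_genesets(
    truth: SimTruth, rng_or_seed: np.random.Generator | int
) -> dict[str, tuple[str, list[str]]]:
    """The planted decay-target set plus random sets drawn from all genes."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    config = truth.config
    genesets: dict[str, tuple[str, list[str]]] = {}
    decay_ids = list(truth.table.index[truth.table["is_decay_target"]])
    if decay_ids:
        genesets[config.planted_set_name] = ("planted decay-target set", decay_ids)
    all_ids = np.array(truth.table.index)
    lo_s, hi_s = config.random_set_size_range
    hi_s = min(hi_s, len(all_ids))
    lo_s = min(lo_s, hi_s)
    for j in range(config.n_random_sets):
        size = int(rng.integers(lo_s, hi_s + 1))
        members = list(rng.choice(all_ids, size=size, replace=False))
        genesets[f"RAND{j + 1:03d}"] = (f"random set {j + 1}", members)
    return genesets


# ---------------------------------------------------------------------------
# Counts and reads


def _nb_draw(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-12:
        return rng.poisson(mu)
    n_param = 1.0 / alpha
    p = n_param / (n_param + mu)
    return rng.negative_binomial(n_param, p)


def simulate_counts(
    truth: SimTruth, seed: int | None = None
) -> tuple[CountMatrix, CountMatrix, pd.Series]:
    """NB count matrices at both levels plus the per-sample library factors.

    Expected means: intron mu = s_sample * intron_mu0 * 2^(Δt * treated),
    exon mu = s_sample * exon_mu0 * 2^((Δt + Δp) * treated).
    """
    config = truth.config
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed + 2_000_003 if seed is not None else None)
    ctrl, trt = truth.sample_names()
    samples = ctrl + trt
    treated = np.array([0] * len(ctrl) + [1] * len(trt))
    lib = np.exp(rng.normal(0.0, config.libsize_sdlog, size=len(samples)))

    t = truth.table
    exon_lfc = (t["delta_t"] + t["delta_p"]).to_numpy()
    intron_lfc = t["delta_t"].to_numpy()
    mu_exon = np.outer(t["exon_mu0"].to_numpy(), lib) * np.power(
        2.0, np.outer(exon_lfc, treated)
    )
    mu_intron = np.outer(t["intron_mu0"].to_numpy(), lib) * np.power(
        2.0, np.outer(intron_lfc, treated)
    )
    counts_exon = _nb_draw(rng, mu_exon, config.dispersion)
    counts_intron = _nb_draw(rng, mu_intron, config.dispersion)

    condition = truth.condition_map()
    cm_exon = CountMatrix(
        "exon",
        pd.DataFrame(counts_exon, index=t.index, columns=samples),
        condition,
    )
    cm_intron = CountMatrix(
        "intron",
        pd.DataFrame(counts_intron, index=t.index, columns=samples),
        condition,
    )
    return cm_exon, cm_intron, pd.Series(lib, index=samples, name="library_factor")


def simulate_reads(
    ann: SimAnnotation, seed: int | None = None
) -> tuple[list[ReadAlignment], CountMatrix, CountMatrix]:
    """Place single-block reads uniformly within each gene's region sets.

    Per-gene read numbers are the NB counts from :func:`simulate_counts`, so
    the returned matrices are the exact bookkeeping truth for the placements;
    reads never leave their source interval (lengths clip to the interval).
    """
    config = ann.truth.config
    if seed is None:
        seed = config.seed
    cm_exon, cm_intron, _ = simulate_counts(ann.truth, seed)
    rng = np.random.default_rng(seed + 3_000_003)
    reads: list[ReadAlignment] = []
    region_sets = {
        "exon": {g.gene_id: constitutive_exons(g) for g in ann.genes},
        "intron": {g.gene_id: constitutive_introns(g) for g in ann.genes},
    }
    for level, cm in (("exon", cm_exon), ("intron", cm_intron)):
        for gene_id in cm.counts.index:
            rs = region_sets[level][gene_id]
            if not rs.intervals:
                if cm.counts.loc[gene_id].sum() > 0:
                    raise ValueError(
                        f"gene {gene_id}: {level} counts but no {level} regions"
                    )
                continue
            lengths = np.array([e - s for s, e in rs.intervals], dtype=float)
            probs = lengths / lengths.sum()
            for sample in cm.counts.columns:
                n = int(cm.counts.loc[gene_id, sample])
                if n == 0:
                    continue
                which = rng.choice(len(rs.intervals), size=n, p=probs)
                for i, w in enumerate(which):
                    s, e = rs.intervals[w]
                    rl = min(config.read_length, e - s)
                    start = int(rng.integers(s, e - rl + 1))
                    reads.append(
                        ReadAlignment(
                            read_id=f"r_{level}_{gene_id}_{sample}_{i}",
                            sample=sample,
                            chrom=rs.chrom,
                            blocks=[(start, start + rl)],
                            mapq_unique=True,
                        )
                    )
    return reads, cm_exon, cm_intron


def write_sam(
    reads: Sequence[ReadAlignment],
    chrom_sizes: dict[str, int],
    path,
    sample: str | None = None,
) -> None:
    """Write placements as a minimal single-end SAM (MAPQ 255, NH:i:1)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for r in reads:
            if sample is not None and r.sample != sample:
                continue
            start, end = r.blocks[0]
            cigar_parts = []
            prev_end = None
            for s, e in r.blocks:
                if prev_end is not None:
                    cigar_parts.append(f"{s - prev_end}N")
                cigar_parts.append(f"{e - s}M")
                prev_end = e
            length = sum(e - s for s, e in r.blocks)
            seq = "A" * length
            mapq = 255 if r.mapq_unique else 0
            nh = 1 if r.mapq_unique else 2
            fh.write(
                f"{r.read_id}\t0\t{r.chrom}\t{start + 1}\t{mapq}\t"
                f"{''.join(cigar_parts)}\t*\t0\t0\t{seq}\t*\tNH:i:{nh}\n"
            )


def scaled_config(config: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
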