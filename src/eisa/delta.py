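"""Exon-intron split analysis: join the two DE levels and read off regulation.

The premise: intron-mapped reads track pre-mRNA and hence transcription, so a
gene's intron-level log2 fold change (Δintron) estimates its transcriptional
response, while the exon-level change (Δexon) tracks mature mRNA.  Genes whose
transcription changes but whose mature mRNA does not are post-transcriptionally
regulated; the strength of the genome-wide Δexon ~ Δintron correlation (R²)
summarises how faithfully transcriptional changes propagate to mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DEResults

CATEGORIES = (
    "post_tx_suppressed",
    "post_tx_enhanced",
    "concordant_up",
    "concordant_down",
    "exon_only_up",
    "exon_only_down",
    "none",
)

DEG_RULES = ("union", "intersection", "all")


class DeltaError(ValueError):
    pass


@dataclass
class CorrelationResult:
    n_genes: int
    r_squared: float
    slope: float
    intercept: float


def classify(
    delta_intron: float, delta_exon: float, deg_intron: bool, deg_exon: bool
) -> str:
    """Regulation category from the two DEG flags and fold-change signs.

    Intron-only changes are post-transcriptional compensation (transcription
    moved, mature mRNA did not): up -> suppressed, down -> enhanced.  Changes
    at both levels with the same sign are concordant (transcriptionally
    driven); exon-only changes lack transcriptional support.  Everything else
    (neither DEG, or discordant double calls) is 'none'.
    """
    if deg_intron and not deg_exon:
        return "post_tx_suppressed" if delta_intron > 0 else "post_tx_enhanced"
    if deg_exon and not deg_intron:
        return "exon_only_up" if delta_exon > 0 else "exon_only_down"
    if deg_intron and deg_exon:
        if delta_intron > 0 and delta_exon > 0:
            return "concordant_up"
        if delta_intron < 0 and delta_exon < 0:
            return "concordant_down"
        return "none"
    return "none"


def build_delta_pairs(
    exon_results: DEResults | pd.DataFrame,
    intron_results: DEResults | pd.DataFrame,
    deg_rule: str = "union",
) -> pd.DataFrame:
    """Per-gene (Δintron, Δexon) pairs for genes tested at both levels.

    ``deg_rule`` selects the gene set: 'union' keeps genes DEG at either
    level (the default for the correlation), 'intersection' at both, 'all'
    every gene tested at both levels.
    """
    if deg_rule not in DEG_RULES:
        raise DeltaError(f"deg_rule must be one of {DEG_RULES}")
    ex = exon_results.table if isinstance(exon_results, DEResults) else exon_results
    it = intron_results.table if isinstance(intron_results, DEResults) else intron_results
    common = ex.index.intersection(it.index)
    if common.empty:
        raise DeltaError(
            "no genes tested at both levels; check that the exon and intron "
            "matrices cover the same gene universe"
        )
    pairs = pd.DataFrame(
        {
            "delta_intron": it.loc[common, "log2FC"],
            "delta_exon": ex.loc[common, "log2FC"],
            "deg_intron": it.loc[common, "is_deg"].astype(bool),
            "deg_exon": ex.loc[common, "is_deg"].astype(bool),
        },
        index=common,
    )
    if deg_rule == "union":
        pairs = pairs[pairs["deg_intron"] | pairs["deg_exon"]]
    elif deg_rule == "intersection":
        pairs = pairs[pairs["deg_intron"] & pairs["deg_exon"]]
    pairs = pairs.copy()
    pairs["category"] = [
        classify(di, de, gi, ge)
        for di, de, gi, ge in zip(
            pairs["delta_intron"], pairs["delta_exon"],
            pairs["deg_intron"], pairs["deg_exon"],
        )
    ]
    pairs.index.name = "gene_id"
    return pairs


def correlation(pairs: pd.DataFrame) -> CorrelationResult:
    """OLS of Δexon on Δintron; R² is the squared Pearson correlation."""
    if len(pairs) < 3:
        raise DeltaError(f"correlation needs >=3 genes, got {len(pairs)}")
    x = pairs["delta_intron"].to_numpy(dtype=float)
    y = pairs["delta_exon"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DeltaError("non-finite fold changes in delta pairs")
    if np.ptp(x) == 0:
        raise DeltaError("zero variance in delta_intron; correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        n_genes=len(pairs),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


@dataclass
class SplitResults:
    """Results of the exon-intron split analysis."""

    pairs: pd.DataFrame
    corr: CorrelationResult
    deg_rule: str
    category_counts: pd.Series = field(default=None)

    def __post_init__(self):
        if self.category_counts is None:
            self.category_counts = (
                self.pairs["category"].value_counts().reindex(CATEGORIES, fill_value=0)
            )

    @property
    def r_squared(self) -> float:
        return self.corr.r_squared

    def genes(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return list(self.pairs.index[self.pairs["category"] == category])

    def summary(self) -> str:
        c = self.corr
        lines = [
            "Exon-intron split analysis",
            "=" * 48,
            f"gene set            {self.deg_rule} of level DEGs (n={c.n_genes})",
            f"R^2 (dExon~dIntron) {c.r_squared:.3f}",
            f"slope / intercept   {c.slope:.3f} / {c.intercept:.3f}",
            "categories:",
        ]
        for cat, n in self.category_counts.items():
            lines.append(f"  {cat:<20s}{int(n)}")
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        return {
            "n_genes": self.corr.n_genes,
            "r_squared": self.corr.r_squared,
            "slope": self.corr.slope,
            "intercept": self.corr.intercept,
            "deg_rule": self.deg_rule,
            "category_counts": {k: int(v) for k, v in self.category_counts.items()},
        }


class ExonIntronSplit:
    """Model object joining exon- and intron-level DE results.

    ``fit()`` builds the (Δintron, Δexon) pairs under ``deg_rule``, fits the
    OLS of Δexon on Δintron, and classifies every paired gene into a
    regulation category.
    """

    def __init__(
        self,
        exon_results: DEResults | pd.DataFrame,
        intron_results: DEResults | pd.DataFrame,
        deg_rule: str = "union",
    ):
        self.exon_results = exon_results
        self.intron_results = intron_results
        self.deg_rule = deg_rule

    def fit(self) -> SplitResults:
        pairs = build_delta_pairs(self.exon_results, self.intron_results, self.deg_rule)
        if len(pairs) < 3:
            raise DeltaError(
                f"only {len(pairs)} genes under deg_rule={self.deg_rule!r}; "
                "too few for a correlation"
            )
        return SplitResults(pairs=pairs, corr=correlation(pairs), deg_rule=self.deg_rule)
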