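"""Hypergeometric over-representation of DEG sets in gene-set collections.

A minimal one-sided ORA: for each gene set, the upper-tail hypergeometric
probability of observing at least the overlap between the study set and the
(universe-intersected) gene set, BH-adjusted across sets.  Sets shrinking
below a minimum size within the universe are skipped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

ADJ_P_CUTOFF = 0.01


class GmtParseError(ValueError):
    pass


def read_gmt(source: str | Path | TextIO | Iterable[str]) -> dict[str, tuple[str, list[str]]]:
    """Parse GMT lines into {set_id: (description, members)} (de-duplicated)."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_gmt(handle)
    collection: dict[str, tuple[str, list[str]]] = {}
    for line_no, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"line {line_no}: GMT lines need set_id, description and >=1 member"
            )
        set_id, desc, *members = fields
        seen: dict[str, None] = {}
        for m in members:
            if m:
                seen.setdefault(m)
        collection[set_id] = (desc, list(seen))
    return collection


def write_gmt(collection: Mapping[str, tuple[str, Sequence[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def hypergeom_enrich(
    study: Iterable[str],
    collection: Mapping[str, tuple[str, Sequence[str]]],
    universe: Iterable[str],
    min_set_size: int = 5,
    adj_p_cutoff: float = ADJ_P_CUTOFF,
) -> pd.DataFrame:
    """One-sided over-representation of ``study`` in each gene set.

    ``study`` must be a subset of ``universe``; set members are intersected
    with the universe before testing.  p = P(X >= overlap) for X hypergeometric
    with (universe_size, set_size, study_size); BH adjustment across the
    tested sets; ``significant`` flags adjusted p <= ``adj_p_cutoff``.
    Rows are sorted by p-value.
    """
    universe = set(universe)
    study = set(study)
    offenders = sorted(study - universe)
    if offenders:
        raise ValueError(
            f"study genes outside the universe: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    n_universe = len(universe)
    n_study = len(study)
    rows = []
    for set_id, (desc, members) in collection.items():
        in_universe = universe.intersection(members)
        if len(in_universe) < min_set_size:
            continue
        overlap = len(study & in_universe)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(in_universe), n_study))
        rows.append(
            {
                "set_id": set_id,
                "description": desc,
                "overlap": overlap,
                "set_size": len(in_universe),
                "study_size": n_study,
                "universe_size": n_universe,
                "pvalue": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["set_id", "description", "overlap", "set_size", "study_size",
                 "universe_size", "pvalue"],
    )
    if not table.empty:
        table["adj_pvalue"] = bh_adjust(table["pvalue"].to_numpy())
        table["significant"] = table["adj_pvalue"] <= adj_p_cutoff
        table = table.sort_values(["pvalue", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        table["adj_pvalue"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
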