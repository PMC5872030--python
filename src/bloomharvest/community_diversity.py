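"""OTU-table summaries: rank-level relative abundance and Shannon diversity.

An OTU table holds marker-gene counts per sample with a rank-delimited
taxonomy string per OTU (k__...;p__...;...;g__...). For stacked-bar style
summaries, counts are aggregated to a chosen rank as per-sample percentages;
taxa that never reach a display threshold (1% by default) in any sample are
pooled into an "other" bucket, and OTUs lacking an assignment at the rank go
to "unmatched".

Diversity is the Shannon index H' = -sum p_i ln p_i (natural log, the
ecological default), bounded by 0 (single taxon) and ln S (uniform).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "RANK_PREFIXES",
    "taxon_at_rank",
    "relative_abundance",
    "shannon_index",
]

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}

OTHER_LABEL = "other"
UNMATCHED_LABEL = "unmatched"


def taxon_at_rank(taxonomy: str, rank: str) -> str | None:
    """Extract the taxon name at a rank from a semicolon-delimited string.

    Returns None when the rank is absent or empty (e.g. a bare "g__").
    """
    prefix = RANK_PREFIXES.get(rank)
    if prefix is None:
        raise ValueError(f"unknown rank {rank!r}; choose from {sorted(RANK_PREFIXES)}")
    for token in str(taxonomy).split(";"):
        token = token.strip()
        if token.startswith(prefix):
            name = token[len(prefix):].strip()
            return name or None
    return None


def relative_abundance(
    table: pd.DataFrame,
    rank: str = "genus",
    min_frac_pct: float = 1.0,
    taxonomy_col: str = "taxonomy",
) -> pd.DataFrame:
    """Aggregate an OTU count table to per-sample percentages at a rank.

    `table` has OTU rows, integer sample columns and a taxonomy column. A
    taxon is kept as its own row if its relative abundance reaches
    `min_frac_pct` (>=, so exactly 1% is retained) in at least one sample;
    the rest are pooled into "other". Columns sum to 100.
    """
    if taxonomy_col not in table.columns:
        raise ValueError(f"missing taxonomy column {taxonomy_col!r}")
    sample_cols = [c for c in table.columns if c != taxonomy_col]
    if not sample_cols:
        raise ValueError("no sample columns")
    counts = table[sample_cols].astype(float)
    if (counts < 0).any().any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    empty = totals[totals <= 0]
    if not empty.empty:
        raise ValueError(f"empty sample column(s): {list(empty.index)}")

    taxa = table[taxonomy_col].map(lambda t: taxon_at_rank(t, rank) or UNMATCHED_LABEL)
    agg = counts.groupby(taxa.values).sum()
    pct = 100.0 * agg / totals

    # "unmatched" is a bookkeeping bucket, not a taxon: never pooled away
    keep = (pct.max(axis=1) >= min_frac_pct) | (pct.index == UNMATCHED_LABEL)
    kept = pct[keep]
    pooled = pct[~keep].sum(axis=0)
    if pooled.any():
        kept = pd.concat(
            [kept, pooled.to_frame(f"{OTHER_LABEL} (<{min_frac_pct:g}%)").T]
        )
    kept.index.name = f"{rank}"
    return kept.sort_index()


def shannon_index(counts) -> float:
    """Shannon diversity H' = -sum p_i ln p_i over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector: diversity undefined")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())
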