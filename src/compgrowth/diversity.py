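"""Alpha diversity and relative-abundance summaries on OTU count tables.

Implements the two estimators used to summarise 16S rRNA communities in
the emulated study — the Shannon diversity index (entropy of the within-
sample OTU relative-abundance distribution, in nats by default) and the
bias-corrected Chao1 richness estimator — plus taxonomic aggregation to
relative abundances at a chosen rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "OtuTable",
    "shannon_index",
    "chao1_richness",
    "relative_abundance",
    "alpha_diversity",
    "rarefy",
]

RANKS = ("phylum", "class", "order", "family", "genus")


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector of OTU counts")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be non-negative integers")
    if c.sum() == 0:
        raise ValueError("all-zero sample: diversity undefined")
    return c.astype(np.int64)


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over OTUs with count > 0.

    Natural-log units (nats) by default; pass ``base`` (e.g. 2) for other
    units. A sample concentrated on a single OTU has H = 0; equal counts
    over S OTUs give the maximum, log S.
    """
    c = _check_counts(counts)
    p = c[c > 0] / c.sum()
    h = float(-(p * np.log(p)).sum())
    return h / float(np.log(base)) if base is not None else h


def chao1_richness(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts.

    Bias-corrected form (default): ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``,
    defined even without doubletons. Classic form ``S_obs + F1^2 / (2 F2)``
    available with ``bias_corrected=False`` (returns S_obs when F1 = 0).
    Always >= the observed richness.
    """
    c = _check_counts(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # classic form falls back when F2 = 0
    return s_obs + f1 * f1 / (2.0 * f2)


@dataclass
class OtuTable:
    """OTU count matrix (OTUs x samples) with per-OTU taxonomy strings.

    ``counts`` is a DataFrame indexed by OTU id with one column per sample;
    ``taxonomy`` a parallel Series of semicolon-separated lineages from
    phylum to genus (lower ranks may be "unclassified"); ``sample_meta``
    an optional per-sample (treatment, day) table indexed by sample id.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("OTU counts must be non-negative integers")
        if not self.counts.index.equals(self.taxonomy.index):
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
        if self.taxonomy.isna().any():
            raise ValueError("taxonomy missing for some OTUs")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def lineage_at(self, rank: str) -> pd.Series:
        """Taxon name of each OTU at ``rank``, padding short lineages with
        'unclassified'."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        i = RANKS.index(rank)

        def pick(lineage: str) -> str:
            parts = [p.strip() for p in lineage.split(";")]
            return parts[i] if i < len(parts) and parts[i] else "unclassified"

        return self.taxonomy.map(pick)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "taxonomy", self.taxonomy)
        out.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_meta: pd.DataFrame | None = None) -> "OtuTable":
        raw = pd.read_csv(path, sep="\t", index_col="otu_id")
        taxonomy = raw.pop("taxonomy")
        return cls(raw.astype(np.int64), taxonomy, sample_meta)


def relative_abundance(table: OtuTable, rank: str = "phylum") -> pd.DataFrame:
    """Aggregate counts by taxon at ``rank`` and normalise per sample.

    Returns a (taxa x samples) DataFrame of proportions; every column sums
    to 1. Aggregation conserves counts before normalising.
    """
    grouped = table.counts.groupby(table.lineage_at(rank)).sum()
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    return grouped / totals


def alpha_diversity(table: OtuTable, shannon_base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon index and bias-corrected Chao1 richness."""
    rows = {
        s: {
            "shannon": shannon_index(table.counts[s].to_numpy(), base=shannon_base),
            "chao1": chao1_richness(table.counts[s].to_numpy()),
        }
        for s in table.samples
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement (seeded).

    Samples with fewer than ``depth`` reads are rejected. Not applied by
    default anywhere in the pipeline; provided for users who want equal
    depths before diversity estimation.
    """
    rng = np.random.default_rng(seed)
    if depth <= 0:
        raise ValueError("depth must be positive")
    new = {}
    for s in table.samples:
        c = table.counts[s].to_numpy()
        total = int(c.sum())
        if total < depth:
            raise ValueError(f"sample {s!r} has only {total} reads < depth {depth}")
        pool = np.repeat(np.arange(c.size), c)
        take = rng.choice(pool, size=depth, replace=False)
        new[s] = np.bincount(take, minlength=c.size)
    counts = pd.DataFrame(new, index=table.counts.index)
    return OtuTable(counts, table.taxonomy.copy(), table.sample_meta)
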