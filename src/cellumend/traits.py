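"""Community-level genomic trait indices.

The community rrn copy number of a sample is the total abundance of
trait-matched taxa divided by their copy-number-adjusted abundance
(aᵢ/cᵢ summed), i.e. the harmonic abundance-weighted mean copy number.
Genome size and GC content are arithmetic abundance-weighted means.
Taxa without a trait match are excluded from both numerator and
denominator; the matched fraction of total abundance is reported as
``coverage``.  All indices are invariant to rescaling the abundances,
so counts and relative abundances give identical results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import CommunityTable, TraitReference

__all__ = [
    "community_rrn_copy_number",
    "abundance_weighted_trait",
    "community_traits",
]

_TRAIT_COLUMNS = {"genome_size": "genome_size_mbp", "gc": "gc_percent"}


def _matched(sample_abundances: pd.Series, ref: TraitReference):
    a = pd.Series(sample_abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be >= 0")
    common = a.index.intersection(ref.table.index)
    a = a.loc[common]
    a = a[a > 0]
    if a.empty:
        raise ValueError("no trait-matched taxon with positive abundance")
    return a, ref.table.loc[a.index]


def community_rrn_copy_number(sample_abundances, ref: TraitReference) -> float:
    """Σaᵢ / Σ(aᵢ/cᵢ) over matched taxa with positive abundance."""
    a, traits = _matched(sample_abundances, ref)
    c = traits["rrn_copies"].to_numpy()
    av = a.to_numpy()
    return float(av.sum() / (av / c).sum())


def abundance_weighted_trait(sample_abundances, ref: TraitReference,
                             trait: str) -> float:
    """Σaᵢxᵢ / Σaᵢ over matched taxa; ``trait`` is 'genome_size' or 'gc'."""
    if trait not in _TRAIT_COLUMNS:
        raise ValueError(f"trait must be one of {sorted(_TRAIT_COLUMNS)}")
    a, traits = _matched(sample_abundances, ref)
    x = traits[_TRAIT_COLUMNS[trait]].to_numpy()
    av = a.to_numpy()
    return float((av * x).sum() / av.sum())


def community_traits(table: CommunityTable, ref: TraitReference) -> pd.DataFrame:
    """Per-sample trait indices with trait-matched abundance coverage."""
    rows = {}
    matched = table.counts.columns.intersection(ref.table.index)
    for sample in table.samples:
        abund = table.counts.loc[sample]
        total = float(abund.sum())
        cov = float(abund.loc[matched].sum() / total) if total > 0 else 0.0
        rows[sample] = {
            "community_rrn": community_rrn_copy_number(abund, ref),
            "weighted_genome_size": abundance_weighted_trait(
                abund, ref, "genome_size"),
            "weighted_gc": abundance_weighted_trait(abund, ref, "gc"),
            "coverage": cov,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
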