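"""Promoter classification and replication-proximity scoring.

High-SA promoters are active promoters whose 500-bp window overlaps a
called SA enrichment region (95th percentile, >= 300 bp) by at least
1 bp.  Early-replication proximity is scored as ordinary feature
occupancy on the EdU log2-enrichment track.  Extragenic enhancers are
those whose window lies at least a minimum distance outside every
transcribed region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .occupancy import OccupancyTable, feature_occupancy
from .region_caller import RegionSet
from .track_io import BinnedTrack, Feature, FeatureSet


@dataclass
class PromoterClassification:
    flags: Dict[str, bool]          # promoter name -> high_SA
    n_high: int
    n_total: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.n_high / self.n_total

    def high_sa_subset(self, promoters: FeatureSet) -> FeatureSet:
        return FeatureSet((f for f in promoters if self.flags.get(f.name)),
                          promoters.chrom_lengths)


def _window(f: Feature, window: int) -> Tuple[int, int]:
    half_lo = window // 2
    return f.anchor - half_lo, f.anchor + (window - half_lo)


def classify_high_sa(promoters: FeatureSet, sa_regions: RegionSet,
                     window: int = 500) -> PromoterClassification:
    """Flag promoters whose window overlaps any SA enrichment region."""
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in sa_regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    flags: Dict[str, bool] = {}
    for f in promoters:
        s, e = _window(f, window)
        flags[f.name] = any(s < re and rs < e
                            for rs, re in by_chrom.get(f.chrom, ()))
    n_high = sum(flags.values())
    return PromoterClassification(flags, n_high, len(promoters))


def replication_scores(features: FeatureSet, edu_enrichment: BinnedTrack,
                       window: int = 500,
                       condition: str = "mock") -> OccupancyTable:
    """Early-replication score = mean EdU log2 enrichment over each window."""
    return feature_occupancy(edu_enrichment, features, window,
                             factor="EdU", condition=condition)


def extragenic_enhancers(enhancers: FeatureSet,
                         transcribed_regions: FeatureSet | None,
                         min_distance: int = 500,
                         window: int = 500) -> FeatureSet:
    """Enhancers whose window sits >= min_distance from every transcript.

    The gap is measured between the enhancer's window edges and the
    transcript interval on the half-open convention; any overlap means a
    gap of 0 and exclusion.  With no transcripts supplied, all enhancers
    are retained.
    """
    if transcribed_regions is None or len(transcribed_regions) == 0:
        return FeatureSet(list(enhancers), enhancers.chrom_lengths)
    tx_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for t in transcribed_regions:
        tx_by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    kept = []
    for f in enhancers:
        s, e = _window(f, window)
        gaps = [max(ts - e, s - te, 0) for ts, te in tx_by_chrom.get(f.chrom, ())]
        if all(g >= min_distance for g in gaps):
            kept.append(f)
    return FeatureSet(kept, enhancers.chrom_lengths)
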