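"""Percentile-threshold enrichment-region calling.

A region is a maximal run of adjacent bins whose values all sit at or
above the genome-wide percentile threshold, kept only if it spans at
least ``min_length`` bp.  This mirrors the common "enrichment in the
95th percentile over regions >= 300 bp" domain definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .track_io import BinnedTrack


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    mean_enrichment: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Called regions plus the calling parameters that produced them."""

    regions: List[Region] = field(default_factory=list)
    threshold: float = float("nan")
    percentile: float = 95.0
    min_length: int = 300

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chrom(self, chrom: str) -> List[Region]:
        return [r for r in self.regions if r.chrom == chrom]


def call_enriched_regions(track: BinnedTrack, percentile: float = 95.0,
                          min_length: int = 300) -> RegionSet:
    """Call enriched regions on a (typically log2-enrichment) track.

    The threshold is the linear-interpolation percentile over all bins of
    all chromosomes; bins ``>=`` threshold count as enriched; runs never
    cross chromosome boundaries; region coordinates are bin-aligned and
    clipped to chromosome ends, and the bp length after clipping must
    reach ``min_length``.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    if min_length < track.bin_width:
        raise ValueError("min_length must be >= bin_width")
    allv = track.all_values()
    if allv.size == 0:
        raise ValueError("empty track")
    threshold = float(np.percentile(allv, percentile))
    w = track.bin_width
    regions: List[Region] = []
    for chrom in track.chrom_lengths:
        vec = track.values[chrom]
        marked = vec >= threshold
        for b0, b1 in _runs(marked):
            start = b0 * w
            end = min(b1 * w, track.chrom_lengths[chrom])
            if end - start >= min_length:
                regions.append(
                    Region(chrom, start, end, float(vec[b0:b1].mean())))
    return RegionSet(regions, threshold, percentile, min_length)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def write_regions_bed(regions: RegionSet, path) -> None:
    """BED4 with the region mean enrichment in the name column."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean_enrichment:.6g}\n")
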