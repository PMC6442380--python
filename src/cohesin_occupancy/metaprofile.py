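"""Strand-oriented meta-feature (meta-gene / meta-origin) profiles.

The profile averages enrichment at fixed oriented offsets around each
feature's anchor: offsets are negative upstream and positive downstream
in the feature's own orientation (reverse-strand windows are flipped).
Features whose meta-analysis windows overlap another input feature's
window are removed before averaging, to keep neighbouring signal from
distorting the mean; windows truncated by a chromosome end are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track_io import BinnedTrack, FeatureSet


@dataclass
class MetaProfile:
    """Mean enrichment by oriented offset (offsets are profile-bin centers)."""

    offsets: np.ndarray       # bp, bin centers, symmetric about 0
    values: np.ndarray        # mean enrichment per offset bin
    n_used: int               # features retained after exclusion
    flank: int
    profile_bin: int

    def __post_init__(self) -> None:
        if self.offsets.shape != self.values.shape:
            raise ValueError("offsets/values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite profile values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.values, "n_used": self.n_used})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def meta_profile(track: BinnedTrack, features: FeatureSet, flank: int = 2000,
                 profile_bin: int = 10) -> MetaProfile:
    """Average enrichment in oriented windows ``[anchor-flank, anchor+flank)``.

    Each profile bin's per-feature value is the unweighted mean of the
    track bins overlapping that bin's genomic interval (the same rule the
    occupancy scorer uses), so aligned windows conserve means across the
    two modules.
    """
    if not (flank >= profile_bin >= track.bin_width):
        raise ValueError("need flank >= profile_bin >= track bin_width")
    if (2 * flank) % profile_bin:
        raise ValueError("profile_bin must divide the window 2*flank")
    # profile-bin centers sit at -flank, ..., 0, ..., +flank so that the
    # zero offset (and reported peak positions) fall on the grid
    offsets = np.arange(-flank, flank + 1, profile_bin)
    lo = profile_bin // 2
    hi = profile_bin - lo
    kept = _exclude_overlapping(features, flank)
    kept = [f for f in kept
            if f.anchor - flank - lo >= 0
            and f.anchor + flank + hi <= track.chrom_lengths[f.chrom]]
    if not kept:
        raise ValueError("no usable features after overlap/edge exclusion")

    w = track.bin_width
    total = np.zeros(offsets.size)
    # csum per chromosome for O(1) bin-range means
    csums = {c: np.concatenate(([0.0], np.cumsum(v)))
             for c, v in track.values.items()}
    for f in kept:
        if f.oriented > 0:
            starts = f.anchor + offsets - lo
        else:  # reversed: oriented offset o sits at genomic anchor - o
            starts = f.anchor - offsets[::-1] - hi + 1
        ends = starts + profile_bin
        i0 = starts // w
        i1 = -(-ends // w)  # ceil division
        cs = csums[f.chrom]
        vals = (cs[i1] - cs[i0]) / (i1 - i0)
        total += vals if f.oriented > 0 else vals[::-1]
    return MetaProfile(offsets.astype(float), total / len(kept),
                       len(kept), flank, profile_bin)


def _exclude_overlapping(features: FeatureSet, flank: int) -> list:
    """Drop every feature whose window intersects another feature's window."""
    feats = list(features)
    windows = sorted(
        ((f.chrom, f.anchor - flank, f.anchor + flank, i)
         for i, f in enumerate(feats)),
        key=lambda t: (t[0], t[1]))
    bad = set()
    for (c1, s1, e1, i1), (c2, s2, e2, i2) in zip(windows, windows[1:]):
        if c1 == c2 and s2 < e1:
            bad.add(i1)
            bad.add(i2)
    return [f for i, f in enumerate(feats) if i not in bad]


def peak_offset(profile: MetaProfile) -> float:
    """Offset (profile-bin center) of the maximum mean enrichment.

    Ties break toward the smallest absolute offset, then toward the
    negative (upstream) one; a flat profile therefore reports the offset
    closest to 0.
    """
    if profile.values.size == 0:
        raise ValueError("empty profile")
    vmax = profile.values.max()
    candidates = profile.offsets[profile.values == vmax]
    order = np.lexsort((candidates, np.abs(candidates)))
    return float(candidates[order[0]])
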