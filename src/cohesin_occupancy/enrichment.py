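"""Depth-normalized log2(IP/input) enrichment tracks.

The enrichment value of bin *b* is::

    log2( ((ip_b + c) / S_ip) / ((input_b + c) / S_in) )

where *c* is a per-bin pseudocount and ``S_ip``, ``S_in`` are the total
counts of each track (pseudocounts included) under total-count
normalization, or 1 when normalization is disabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_io import BinnedTrack


@dataclass(frozen=True)
class EnrichmentParams:
    pseudocount: float = 1.0
    normalization: str = "total-count"  # or "none"

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.normalization not in ("total-count", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def log2_enrichment(ip: BinnedTrack, input_track: BinnedTrack,
                    params: EnrichmentParams | None = None) -> BinnedTrack:
    """log2 enrichment of an IP track over its chromatin input."""
    params = params or EnrichmentParams()
    if not ip.same_geometry(input_track):
        raise ValueError("IP and input tracks have mismatched geometry")
    c = params.pseudocount
    if c == 0.0:
        for track in (ip, input_track):
            if any((v == 0).any() for v in track.values.values()):
                raise ValueError(
                    "pseudocount 0 with zero-count bins gives infinite enrichment")
    if params.normalization == "total-count":
        nb = sum(v.size for v in ip.values.values())
        s_ip = ip.total() + c * nb
        s_in = input_track.total() + c * nb
    else:
        s_ip = s_in = 1.0
    out = {}
    for chrom in ip.chrom_lengths:
        a = (ip.values[chrom] + c) / s_ip
        b = (input_track.values[chrom] + c) / s_in
        out[chrom] = np.log2(a / b)
    return ip.copy_with(out)
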