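"""Per-feature occupancy scoring and subunit-proportionality summaries.

Occupancy of a feature is the unweighted mean of the enrichment-track
bins overlapping a fixed window (default 500 bp) centered on the
feature's anchor.  Between-factor proportionality at a feature class is
summarised by the through-origin least-squares slope — the natural ratio
estimate when comparing subunit stoichiometry — plus the Pearson
correlation of the paired occupancies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .track_io import BinnedTrack, FeatureSet

COLUMNS = ["feature", "class", "factor", "condition", "value"]


@dataclass
class OccupancyTable:
    """Long-format occupancy values, one row per (feature, factor, condition)."""

    data: pd.DataFrame
    window: int = 500

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        if not np.all(np.isfinite(self.data["value"])):
            raise ValueError("non-finite occupancy values")

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, class_label: str | None = None, factor: str | None = None,
               condition: str | None = None) -> pd.DataFrame:
        df = self.data
        if class_label is not None:
            df = df[df["class"] == class_label]
        if factor is not None:
            df = df[df["factor"] == factor]
        if condition is not None:
            df = df[df["condition"] == condition]
        return df

    @staticmethod
    def concat(tables: list["OccupancyTable"]) -> "OccupancyTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        return OccupancyTable(
            pd.concat([t.data for t in tables], ignore_index=True),
            tables[0].window)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path, window: int = 500) -> "OccupancyTable":
        return OccupancyTable(pd.read_csv(path, sep="\t"), window)


@dataclass(frozen=True)
class ProportionalityResult:
    class_label: str
    factor_a: str
    factor_b: str
    slope: float
    pearson_r: float
    n: int


def feature_occupancy(track: BinnedTrack, features: FeatureSet,
                      window: int = 500, factor: str = "factor",
                      condition: str = "mock") -> OccupancyTable:
    """Mean enrichment over a window centered on each feature anchor.

    Windows extending past a chromosome end are clipped and averaged over
    the covered bins only.
    """
    if window < track.bin_width:
        raise ValueError("window must be >= bin_width")
    w = track.bin_width
    half_lo = window // 2
    half_hi = window - half_lo
    rows = []
    for f in features:
        if f.chrom not in track.chrom_lengths:
            raise ValueError(f"feature {f.name} on unknown chromosome {f.chrom}")
        length = track.chrom_lengths[f.chrom]
        s = max(0, f.anchor - half_lo)
        e = min(length, f.anchor + half_hi)
        if e <= s:
            raise ValueError(f"feature {f.name}: window empty after clipping")
        vec = track.values[f.chrom]
        value = float(vec[s // w: math.ceil(e / w)].mean())
        rows.append((f.name, f.class_label, factor, condition, value))
    return OccupancyTable(pd.DataFrame(rows, columns=COLUMNS), window)


def occupancy_summary(table: OccupancyTable,
                      class_label: str) -> pd.DataFrame:
    """Median, quartiles and n per (factor, condition) for one class.

    Quantiles use linear interpolation between order statistics.
    """
    df = table.subset(class_label=class_label)
    if df.empty:
        raise ValueError(f"no features of class {class_label!r}")
    out = (
        df.groupby(["factor", "condition"])["value"]
        .agg(median="median",
             q1=lambda v: float(np.percentile(v, 25)),
             q3=lambda v: float(np.percentile(v, 75)),
             n="size")
        .reset_index()
    )
    out.insert(0, "class", class_label)
    return out


def subunit_proportionality(table: OccupancyTable, factor_a: str,
                            factor_b: str, class_label: str,
                            condition: str = "mock") -> ProportionalityResult:
    """Through-origin slope of factor_b on factor_a over one feature class.

    slope = sum(a_i * b_i) / sum(a_i^2), the least-squares ratio estimate
    with a zero intercept.
    """
    a_df = table.subset(class_label, factor_a, condition).set_index("feature")
    b_df = table.subset(class_label, factor_b, condition).set_index("feature")
    shared = a_df.index.intersection(b_df.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 features scored for both factors")
    a = a_df.loc[shared, "value"].to_numpy()
    b = b_df.loc[shared, "value"].to_numpy()
    denom = float(np.dot(a, a))
    if denom == 0.0:
        raise ValueError(f"all {factor_a} occupancies are zero; slope undefined")
    slope = float(np.dot(a, b)) / denom
    r = float(stats.pearsonr(a, b).statistic) if np.std(a) > 0 and np.std(b) > 0 \
        else float("nan")
    return ProportionalityResult(class_label, factor_a, factor_b,
                                 slope, r, len(shared))
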