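"""Synthetic genome layouts and ChIP-seq coverage tracks with ground truth.

The generator emulates the signal structure of cohesin/origin ChIP-seq in
a compact genome: replication-origin centers spaced along chromosomes,
enhancers clustered around origins, a small origin-proximal and a large
origin-distal promoter population, origin-distal PREs, transcribed
regions kept away from origins, and random control intervals.

Per-factor IP/input count tracks follow a log2-enrichment expectation

    mu(b) = baseline + sum_features A_class * depletion * exp(-d/lambda)
            * stoich(class, d) * gauss(bin - oriented peak position)

where *d* is the feature's distance to the nearest origin center.  IP
counts are negative-binomial around ``read_depth * 2**mu`` (Poisson when
the dispersion is 0); the input is flat at ``read_depth``.  A noise-free
mode returns the exact expectations, which downstream modules recover
bit-for-bit; every simulated feature is recorded in a truth table with
its origin distance and planted per-factor expected occupancy.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .track_io import BinnedTrack, Feature, FeatureSet, n_bins, write_bed, \
    write_chrom_sizes


class LayoutError(RuntimeError):
    """Genome too small for the requested feature counts/separations."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults are a desk-scale stand-in for the fly-cell feature census
    (78 origins / 2353 enhancers / 7389 promoters / 195 PREs / 6892
    random controls on ~120 Mb): two 2-Mb chromosomes carrying 10
    origins, 60 enhancers, 300 promoters, 20 PREs and 100 random
    intervals, with all between-feature distances scaled accordingly.
    """

    chromosome_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr2L": 2_000_000, "chr2R": 2_000_000})
    n_origins: int = 10
    n_enhancers: int = 60
    n_promoters: int = 300
    n_pres: int = 20
    n_random: int = 100
    n_transcripts: int = 120
    transcript_length: int = 10_000
    transcript_min_origin_distance: int = 12_000
    origin_min_separation: int = 100_000
    enhancer_origin_sd: int = 10_000
    promoter_proximal_fraction: float = 0.15
    proximal_max_distance: int = 15_000
    distal_min_distance: int = 40_000
    feature_window: int = 500
    bin_width: int = 10
    read_depth: float = 50.0
    noise_dispersion: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_origins, self.n_enhancers, self.n_promoters,
                  self.n_pres, self.n_random, self.n_transcripts)
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be >= 0")
        if not (0.0 <= self.promoter_proximal_fraction <= 1.0):
            raise ValueError("promoter_proximal_fraction must be in [0, 1]")
        if self.proximal_max_distance >= self.distal_min_distance:
            raise ValueError("proximal_max_distance must be < distal_min_distance")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if min(self.chromosome_lengths.values()) <= 2 * self.distal_min_distance:
            raise ValueError("chromosomes too short for the distance rules")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @staticmethod
    def from_dict(d: Mapping) -> "SimulationConfig":
        return SimulationConfig(**dict(d))


@dataclass
class FactorParams:
    """Planted signal parameters for one ChIP'd factor."""

    name: str
    baseline: float = 0.0
    class_amplitude: Dict[str, float] = field(default_factory=dict)
    peak_offset: int = 0          # bp, oriented (negative = upstream)
    peak_sd: float = 60.0         # bp
    origin_decay_length: float = math.inf   # lambda; inf = no decay
    stoichiometry_distal: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_sd <= 0:
            raise ValueError("peak_sd must be > 0")
        if not self.origin_decay_length > 0:
            raise ValueError("origin_decay_length must be > 0 (may be inf)")
        if not (0.0 <= self.stoichiometry_distal <= 1.0):
            raise ValueError("stoichiometry_distal must be in [0, 1]")


@dataclass
class DepletionSpec:
    """Per-factor, per-class amplitude multipliers for one condition.

    ``multipliers[factor][class]`` rescales that factor's planted
    amplitude on that feature class; missing entries default to 1 (mock).
    Promoters may be addressed jointly ("promoter") or split into
    "promoter_proximal"/"promoter_distal" keys, which take precedence —
    depletions in the emulated system move occupancy in opposite
    directions at origin-proximal versus origin-distal promoters.
    """

    condition: str = "mock"
    multipliers: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for factor, classes in self.multipliers.items():
            for cls, m in classes.items():
                if m < 0:
                    raise ValueError(
                        f"negative multiplier for {factor}/{cls}")

    def factor_multiplier(self, factor: str, class_label: str,
                          proximal: bool) -> float:
        classes = self.multipliers.get(factor, {})
        if class_label == "promoter":
            key = "promoter_proximal" if proximal else "promoter_distal"
            if key in classes:
                return classes[key]
        return classes.get(class_label, 1.0)


def mock_condition() -> DepletionSpec:
    return DepletionSpec("mock", {})


def default_factors() -> Dict[str, FactorParams]:
    """Factor parameter set emulating the cohesin/origin signal structure.

    SA decays steeply with origin distance and is absent from distal
    promoters; the ring subunits and the loader decay gently, with SMC1
    subproportional (half the Rad21 ratio) at distal promoters.  Peak
    offsets follow the reported meta-promoter positions (Nipped-B/Rad21
    -70 bp, SMC1 -35 bp, SA downstream near +100, Pol II +65).  SA's
    footprint is broad (sd 400 bp), giving the contiguous >=300 bp
    enrichment domains around origins and enhancer clusters that the
    percentile region caller is designed to pick up; the other factors
    have sharp promoter-scale footprints (sd 60 bp) so that meta-profile
    peak positions are resolvable at 10-bp bins.
    """
    return {
        "SA": FactorParams(
            "SA",
            class_amplitude={"promoter": 2.0, "enhancer": 2.5,
                             "PRE": 2.0, "origin": 3.0},
            peak_offset=100, peak_sd=400.0, origin_decay_length=20_000,
            stoichiometry_distal=0.0),
        "Rad21": FactorParams(
            "Rad21",
            class_amplitude={"promoter": 2.0, "enhancer": 3.0,
                             "PRE": 2.5, "origin": 2.0},
            peak_offset=-70, origin_decay_length=200_000,
            stoichiometry_distal=1.0),
        "SMC1": FactorParams(
            "SMC1",
            class_amplitude={"promoter": 2.0, "enhancer": 3.2,
                             "PRE": 2.8, "origin": 1.8},
            peak_offset=-35, origin_decay_length=200_000,
            stoichiometry_distal=0.5),
        "Nipped-B": FactorParams(
            "Nipped-B",
            class_amplitude={"promoter": 2.5, "enhancer": 3.5,
                             "PRE": 3.0, "origin": 2.5},
            peak_offset=-70, origin_decay_length=200_000,
            stoichiometry_distal=1.0),
        "Rpb3": FactorParams(
            "Rpb3",
            class_amplitude={"promoter": 2.5, "enhancer": 1.0},
            peak_offset=65, origin_decay_length=math.inf,
            stoichiometry_distal=1.0),
    }


def sa_depletion_condition() -> DepletionSpec:
    """Emulated SA-RNAi shift: cohesin leaves origin-proximal features and
    rises at origin-distal promoters."""
    shift = {"enhancer": 0.6, "origin": 0.6, "PRE": 0.7,
             "promoter_proximal": 0.7, "promoter_distal": 1.3}
    return DepletionSpec("iSA", {
        "SA": {c: 0.2 for c in
               ("promoter", "enhancer", "PRE", "origin")},
        "Rad21": dict(shift),
        "SMC1": dict(shift),
        "Nipped-B": dict(shift),
    })


def child_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic stream per (seed, labels), independent across labels."""
    tags = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


# ---------------------------------------------------------------------------
# layout

_MAX_TRIES = 10_000


def _chrom_arrays(config: SimulationConfig) -> Tuple[List[str], np.ndarray]:
    names = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in names])
    return names, lengths


def generate_layout(config: SimulationConfig
                    ) -> Tuple[FeatureSet, pd.DataFrame]:
    """Place all feature classes and return them with a truth table.

    The truth table has one row per feature: class, chrom, anchor,
    strand, and brute-force distance to the nearest origin center.
    """
    rng = child_rng(config.seed, "layout")
    names, lengths = _chrom_arrays(config)
    margin = max(config.feature_window, 1)
    fw = config.feature_window

    origins = _place_origins(config, rng, names, lengths, margin)
    origin_pos: Dict[str, np.ndarray] = {
        c: np.sort(np.array([p for cc, p in origins if cc == c], dtype=int))
        for c in names}

    def dist_to_origin(chrom: str, pos: int) -> int:
        pts = origin_pos[chrom]
        if pts.size == 0:
            return 2**62
        return int(np.min(np.abs(pts - pos)))

    feats: List[Feature] = []
    rows: List[tuple] = []

    def add(chrom: str, anchor: int, strand: str, cls: str, name: str,
            start: int | None = None, end: int | None = None) -> None:
        if start is None:
            start = anchor - fw // 2
            end = anchor + fw - fw // 2
        feats.append(Feature(chrom, start, end, strand, cls, name, anchor))
        rows.append((name, cls, chrom, anchor, strand,
                     dist_to_origin(chrom, anchor)))

    for i, (chrom, pos) in enumerate(origins):
        add(chrom, pos, ".", "origin", f"ori_{i:04d}")

    def uniform_anchor() -> Tuple[str, int]:
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        chrom = names[ci]
        return chrom, int(rng.integers(margin, lengths[ci] - margin))

    # enhancers: Gaussian offsets from randomly chosen origins
    for i in range(config.n_enhancers):
        if not origins:
            raise LayoutError("enhancers require at least one origin")
        for _ in range(_MAX_TRIES):
            chrom, opos = origins[rng.integers(len(origins))]
            pos = int(round(opos + rng.normal(0.0, config.enhancer_origin_sd)))
            if margin <= pos <= config.chromosome_lengths[chrom] - margin:
                break
        else:
            raise LayoutError("could not place enhancer inside chromosome")
        add(chrom, pos, ".", "enhancer", f"enh_{i:04d}")

    # promoters: proximal fraction near origins, remainder origin-distal
    n_prox = round(config.promoter_proximal_fraction * config.n_promoters)
    for i in range(config.n_promoters):
        proximal = i < n_prox
        for _ in range(_MAX_TRIES):
            if proximal:
                if not origins:
                    raise LayoutError("proximal promoters require origins")
                chrom, opos = origins[rng.integers(len(origins))]
                pos = int(opos + rng.integers(-config.proximal_max_distance,
                                              config.proximal_max_distance + 1))
                ok = (margin <= pos <= config.chromosome_lengths[chrom] - margin
                      and dist_to_origin(chrom, pos)
                      <= config.proximal_max_distance)
            else:
                chrom, pos = uniform_anchor()
                ok = dist_to_origin(chrom, pos) >= config.distal_min_distance
            if ok:
                break
        else:
            raise LayoutError("could not satisfy promoter distance rules")
        strand = "+" if rng.integers(2) else "-"
        # interval runs downstream from the TSS (BED convention: the TSS
        # is `start` on "+" and `end-1` on "-"); scoring windows are
        # centered on the anchor, not on the interval
        start = pos if strand == "+" else pos - fw + 1
        add(chrom, pos, strand, "promoter", f"pro_{i:04d}",
            start=start, end=start + fw)

    for i in range(config.n_pres):
        for _ in range(_MAX_TRIES):
            chrom, pos = uniform_anchor()
            if dist_to_origin(chrom, pos) >= config.distal_min_distance:
                break
        else:
            raise LayoutError("could not place origin-distal PRE")
        add(chrom, pos, ".", "PRE", f"pre_{i:04d}")

    for i in range(config.n_random):
        chrom, pos = uniform_anchor()
        add(chrom, pos, ".", "random", f"ran_{i:04d}")

    # transcribed regions are kept away from origins (transcription pushes
    # licensed helicases out of gene bodies, so early replication stays
    # extragenic); midpoint-anchored intervals of transcript_length
    half_tx = config.transcript_length // 2
    for i in range(config.n_transcripts):
        for _ in range(_MAX_TRIES):
            ci = rng.choice(len(names), p=lengths / lengths.sum())
            chrom = names[ci]
            pos = int(rng.integers(half_tx, lengths[ci] - half_tx))
            if dist_to_origin(chrom, pos) \
                    >= config.transcript_min_origin_distance:
                break
        else:
            raise LayoutError("could not place origin-distal transcript")
        add(chrom, pos, ".", "transcript", f"tx_{i:04d}",
            start=pos - half_tx, end=pos - half_tx + config.transcript_length)

    truth = pd.DataFrame(
        rows, columns=["feature", "class", "chrom", "anchor", "strand",
                       "origin_distance"])
    return FeatureSet(feats, config.chromosome_lengths), truth


def _place_origins(config, rng, names, lengths, margin
                   ) -> List[Tuple[str, int]]:
    placed: List[Tuple[str, int]] = []
    for _ in range(config.n_origins):
        for _ in range(_MAX_TRIES):
            ci = rng.choice(len(names), p=lengths / lengths.sum())
            chrom = names[ci]
            pos = int(rng.integers(margin, lengths[ci] - margin))
            if all(c != chrom or abs(p - pos) >= config.origin_min_separation
                   for c, p in placed):
                placed.append((chrom, pos))
                break
        else:
            raise LayoutError(
                "could not place origins with the requested separation")
    return placed


# ---------------------------------------------------------------------------
# planted expectations and truth occupancy


def _is_proximal(config: SimulationConfig, origin_distance: float) -> bool:
    return origin_distance <= config.proximal_max_distance


def planted_amplitude(cls: str, origin_distance: float, params: FactorParams,
                      depletion: DepletionSpec,
                      config: SimulationConfig) -> float:
    """Peak amplitude (log2 units) this feature contributes, after class
    amplitude, depletion multiplier, origin-distance decay and promoter
    stoichiometry."""
    amp = params.class_amplitude.get(cls, 0.0)
    if amp == 0.0:
        return 0.0
    proximal = _is_proximal(config, origin_distance)
    amp *= depletion.factor_multiplier(params.name, cls, proximal)
    if math.isfinite(params.origin_decay_length):
        amp *= math.exp(-origin_distance / params.origin_decay_length)
    if cls == "promoter" and not proximal:
        amp *= params.stoichiometry_distal
    return amp


def truth_occupancy(truth: pd.DataFrame, factors: Mapping[str, FactorParams],
                    conditions: Sequence[DepletionSpec],
                    config: SimulationConfig) -> pd.DataFrame:
    """Truth table extended with planted expected occupancy per
    factor/condition (column ``<factor>:<condition>``), i.e. the planted
    peak amplitude above baseline."""
    out = truth.copy()
    for cond in conditions:
        for name, params in factors.items():
            out[f"{name}:{cond.condition}"] = [
                planted_amplitude(cls, d, params, cond, config)
                for cls, d in zip(truth["class"], truth["origin_distance"])]
    return out


# ---------------------------------------------------------------------------
# track simulation


def expected_log2_track(layout: FeatureSet, params: FactorParams,
                        depletion: DepletionSpec,
                        config: SimulationConfig,
                        truth: pd.DataFrame | None = None) -> BinnedTrack:
    """Per-bin expected log2 enrichment mu(b) for one factor/condition."""
    if truth is None:
        truth = _layout_truth(layout, config)
    dist = dict(zip(truth["feature"], truth["origin_distance"]))
    w = config.bin_width
    track = BinnedTrack(w, dict(config.chromosome_lengths))
    for chrom in track.chrom_lengths:
        track.values[chrom][:] = params.baseline
    sd = params.peak_sd
    # truncate each peak at 8.5 sd: the clipped tail is < 2e-16 of the
    # amplitude, below double-precision resolution of the summed track
    reach = int(math.ceil(8.5 * sd / w)) + 1
    for f in layout:
        amp = planted_amplitude(f.class_label, dist[f.name], params,
                                depletion, config)
        if amp == 0.0:
            continue
        center = f.anchor + f.oriented * params.peak_offset
        vec = track.values[f.chrom]
        c_bin = center // w
        i0 = max(0, c_bin - reach)
        i1 = min(vec.size, c_bin + reach + 1)
        centers = np.arange(i0, i1) * w + w / 2.0
        vec[i0:i1] += amp * np.exp(-((centers - center) ** 2) / (2 * sd * sd))
    return track


def _layout_truth(layout: FeatureSet, config: SimulationConfig) -> pd.DataFrame:
    origin_pos: Dict[str, List[int]] = {}
    for f in layout:
        if f.class_label == "origin":
            origin_pos.setdefault(f.chrom, []).append(f.anchor)
    rows = []
    for f in layout:
        pts = np.array(origin_pos.get(f.chrom, []), dtype=int)
        d = int(np.min(np.abs(pts - f.anchor))) if pts.size else 2**62
        rows.append((f.name, f.class_label, f.chrom, f.anchor, f.strand, d))
    return pd.DataFrame(rows, columns=["feature", "class", "chrom", "anchor",
                                       "strand", "origin_distance"])


def _sample_counts(mean: np.ndarray, dispersion: float,
                   rng: np.random.Generator) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion == 0.0:
        return rng.poisson(mean).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def simulate_factor_tracks(layout: FeatureSet, params: FactorParams,
                           depletion: DepletionSpec, config: SimulationConfig,
                           noise_free: bool = False,
                           rng: np.random.Generator | None = None,
                           truth: pd.DataFrame | None = None
                           ) -> Tuple[BinnedTrack, BinnedTrack]:
    """IP and input count tracks for one factor under one condition.

    In noise-free mode the returned tracks are the exact expectations
    ``read_depth * 2**mu`` and ``read_depth``.
    """
    mu = expected_log2_track(layout, params, depletion, config, truth)
    if rng is None:
        rng = child_rng(config.seed, "tracks", params.name, depletion.condition)
    ip_vals, in_vals = {}, {}
    for chrom in mu.chrom_lengths:
        ip_mean = config.read_depth * np.exp2(mu.values[chrom])
        in_mean = np.full_like(ip_mean, config.read_depth)
        if noise_free:
            ip_vals[chrom], in_vals[chrom] = ip_mean, in_mean
        else:
            ip_vals[chrom] = _sample_counts(ip_mean, config.noise_dispersion, rng)
            in_vals[chrom] = _sample_counts(in_mean, config.noise_dispersion, rng)
    return mu.copy_with(ip_vals), mu.copy_with(in_vals)


def simulate_early_replication(layout: FeatureSet, lambda_rep: float,
                               config: SimulationConfig,
                               amplitude: float = 3.0,
                               noise_free: bool = False,
                               rng: np.random.Generator | None = None
                               ) -> Tuple[BinnedTrack, BinnedTrack]:
    """EdU-style early-replication track pair.

    The expected log2 enrichment of bin *b* is
    ``amplitude * exp(-d_origin(b)/lambda_rep)`` with *d* the distance
    from the bin center to the nearest origin center — monotone
    non-increasing in origin distance.
    """
    if not lambda_rep > 0:
        raise ValueError("lambda_rep must be > 0 (may be inf)")
    if rng is None:
        rng = child_rng(config.seed, "tracks", "EdU", "mock")
    w = config.bin_width
    origin_pos: Dict[str, np.ndarray] = {}
    for f in layout:
        if f.class_label == "origin":
            origin_pos.setdefault(f.chrom, []).append(f.anchor)
    mu = BinnedTrack(w, dict(config.chromosome_lengths))
    for chrom, length in config.chromosome_lengths.items():
        centers = np.arange(n_bins(length, w)) * w + w / 2.0
        pts = np.sort(np.array(origin_pos.get(chrom, []), dtype=float))
        if pts.size == 0:
            continue
        idx = np.searchsorted(pts, centers)
        left = pts[np.clip(idx - 1, 0, pts.size - 1)]
        right = pts[np.clip(idx, 0, pts.size - 1)]
        d = np.minimum(np.abs(centers - left), np.abs(centers - right))
        if math.isinf(lambda_rep):
            mu.values[chrom][:] = amplitude
        else:
            mu.values[chrom][:] = amplitude * np.exp(-d / lambda_rep)
    ip_vals, in_vals = {}, {}
    for chrom in mu.chrom_lengths:
        ip_mean = config.read_depth * np.exp2(mu.values[chrom])
        in_mean = np.full_like(ip_mean, config.read_depth)
        if noise_free:
            ip_vals[chrom], in_vals[chrom] = ip_mean, in_mean
        else:
            ip_vals[chrom] = _sample_counts(ip_mean, config.noise_dispersion, rng)
            in_vals[chrom] = _sample_counts(in_mean, config.noise_dispersion, rng)
    return mu.copy_with(ip_vals), mu.copy_with(in_vals)


# ---------------------------------------------------------------------------
# run-directory export


def write_layout(run_dir, layout: FeatureSet, truth: pd.DataFrame,
                 config: SimulationConfig) -> Dict[str, str]:
    """BED6 per class, truth TSV, chrom.sizes and a JSON config snapshot."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    for cls in layout.classes:
        p = run_dir / f"{cls}.bed"
        write_bed(layout.by_class(cls), p)
        paths[f"bed:{cls}"] = str(p)
    truth_path = run_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)
    sizes = run_dir / "chrom.sizes"
    write_chrom_sizes(config.chromosome_lengths, sizes)
    paths["chrom_sizes"] = str(sizes)
    cfg = run_dir / "config.json"
    config.to_json(cfg)
    paths["config"] = str(cfg)
    return paths
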