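"""Validation experiments: parameter recovery, calibration and oracle
agreement on synthetic data.

Each function runs a self-contained experiment at the package's default
study conditions and returns plain numbers.  They are the computational
substance behind the verification suite and the results-reproduction
script; all randomness descends from an explicit seed.
"""

from __future__ import annotations

import dataclasses
from math import comb
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from .classify import classify_high_sa, extragenic_enhancers, replication_scores
from .compare_stats import fisher_viability, signed_rank_p
from .enrichment import EnrichmentParams, log2_enrichment
from .metaprofile import meta_profile, peak_offset
from .occupancy import OccupancyTable, feature_occupancy, subunit_proportionality
from .reference import (brute_force_regions, fisher_exact_enumeration,
                        wilcoxon_exact_enumeration)
from .region_caller import call_enriched_regions
from .synthetic import (DepletionSpec, SimulationConfig, child_rng,
                        default_factors, generate_layout, mock_condition,
                        simulate_early_replication, simulate_factor_tracks)
from .track_io import BinnedTrack, FeatureSet

#: simulated track pairs are depth-matched by construction, so enrichment
#: is computed without a depth correction in every experiment
ENR = EnrichmentParams(pseudocount=1.0, normalization="none")

LAMBDA_REP = 15_000.0


def high_sa_percentage(n_high: int = 895, n_total: int = 7398) -> float:
    """Percentage of active promoters classified high-SA from two counts.

    Defaults are the promoter census of the fly-cell study this package
    re-implements (895 high-SA of 7398 active promoters).
    """
    from .classify import PromoterClassification
    return PromoterClassification({}, n_high, n_total).percentage


# ---------------------------------------------------------------------------
# region caller vs brute force


def random_test_track(rng: np.random.Generator) -> BinnedTrack:
    """A small track mixing constant stretches, spikes and noise, with
    frequent exact ties to exercise the >=-threshold rule."""
    n_chrom = int(rng.integers(1, 4))
    w = int(rng.choice([10, 50, 100]))
    lengths, values = {}, {}
    for ci in range(n_chrom):
        nb = int(rng.integers(1, 501 // n_chrom))
        name = f"c{ci}"
        # chromosome length not always a bin multiple
        lengths[name] = nb * w - int(rng.integers(0, w))
        style = rng.integers(4)
        if style == 0:
            vec = np.full(nb, float(rng.integers(-2, 3)))
        elif style == 1:
            vec = rng.choice([0.0, 1.0, 2.0, 5.0], size=nb)
        elif style == 2:
            vec = rng.normal(size=nb)
        else:
            vec = np.zeros(nb)
            for _ in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, nb))
                e = min(nb, s + int(rng.integers(1, 40)))
                vec[s:e] = float(rng.integers(1, 10))
        values[name] = vec[: (lengths[name] + w - 1) // w]
        if lengths[name] == 0:
            lengths[name] = w
            values[name] = vec[:1]
    return BinnedTrack(w, lengths, values)


def region_caller_agreement(n_tracks: int = 1000,
                            seed: int = 0) -> Tuple[int, int]:
    """Count tracks on which the caller matches the brute-force oracle."""
    rng = child_rng(seed, "region-oracle")
    agree = 0
    for _ in range(n_tracks):
        track = random_test_track(rng)
        percentile = float(rng.choice([50.0, 90.0, 95.0]))
        min_length = int(rng.choice([1, 2, 6])) * track.bin_width
        called = call_enriched_regions(track, percentile, min_length)
        got = [(r.chrom, r.start, r.end) for r in called]
        expected = brute_force_regions(track, percentile, min_length)
        agree += got == expected
    return agree, n_tracks


# ---------------------------------------------------------------------------
# meta-profile peak recovery


def peak_recovery_noise_free(seed: int = 0) -> float:
    """Recovered promoter peak offset from a noise-free default run
    (Rad21, planted at -70 bp)."""
    cfg = SimulationConfig(seed=seed)
    layout, truth = generate_layout(cfg)
    params = default_factors()["Rad21"]
    ip, inp = simulate_factor_tracks(layout, params, mock_condition(), cfg,
                                     noise_free=True, truth=truth)
    enr = log2_enrichment(ip, inp, EnrichmentParams(0.0, "none"))
    prof = meta_profile(enr, layout.by_class("promoter"), 2000, 10)
    return peak_offset(prof)


def peak_recovery_noisy(n_reps: int = 100, seed: int = 0
                        ) -> Tuple[float, np.ndarray]:
    """Median |recovered - planted| over noisy default replicates."""
    planted = default_factors()["Rad21"].peak_offset
    errors = []
    for i in range(n_reps):
        cfg = SimulationConfig(seed=seed + i)
        layout, truth = generate_layout(cfg)
        params = default_factors()["Rad21"]
        ip, inp = simulate_factor_tracks(layout, params, mock_condition(),
                                         cfg, truth=truth)
        enr = log2_enrichment(ip, inp, ENR)
        prof = meta_profile(enr, layout.by_class("promoter"), 2000, 10)
        errors.append(abs(peak_offset(prof) - planted))
    errors = np.array(errors)
    return float(np.median(errors)), errors


# ---------------------------------------------------------------------------
# stoichiometry recovery


def stoichiometry_recovery(seed: int = 0) -> Dict[str, float]:
    """Through-origin SMC1-vs-Rad21 occupancy slopes at origin-distal and
    origin-proximal promoters (planted ratios 0.5 and 1.0)."""
    cfg = SimulationConfig(seed=seed)
    layout, truth = generate_layout(cfg)
    promoters = layout.by_class("promoter")
    factors = default_factors()
    tables = []
    for name in ("Rad21", "SMC1"):
        ip, inp = simulate_factor_tracks(layout, factors[name],
                                         mock_condition(), cfg, truth=truth)
        enr = log2_enrichment(ip, inp, ENR)
        tables.append(feature_occupancy(enr, promoters, 500, factor=name))
    table = OccupancyTable.concat(tables)
    dist = truth.set_index("feature").loc[table.data["feature"],
                                          "origin_distance"].to_numpy()
    out = {}
    for label, mask in (("distal", dist > cfg.proximal_max_distance),
                        ("proximal", dist <= cfg.proximal_max_distance)):
        sub = OccupancyTable(table.data[mask], table.window)
        res = subunit_proportionality(sub, "Rad21", "SMC1", "promoter")
        out[f"slope_{label}"] = res.slope
        out[f"n_{label}"] = res.n
    return out


# ---------------------------------------------------------------------------
# Wilcoxon calibration and power


def _calibration_layout(seed: int):
    """60 isolated scoring windows on a small genome.

    Features are thinned so no two windows share track bins: the paired
    test's independence assumption holds by design in the calibration
    experiment (clustered features with overlapping windows violate it).
    """
    cfg = SimulationConfig(
        chromosome_lengths={"chr": 600_000}, n_origins=3, n_enhancers=0,
        n_promoters=0, n_pres=0, n_random=90, n_transcripts=0,
        origin_min_separation=80_000, proximal_max_distance=15_000,
        distal_min_distance=30_000, seed=seed)
    layout, truth = generate_layout(cfg)
    feats = sorted(layout.by_class("random"), key=lambda f: f.anchor)
    isolated = [f for i, f in enumerate(feats)
                if (i == 0 or f.anchor - feats[i - 1].anchor >= 500)
                and (i == len(feats) - 1
                     or feats[i + 1].anchor - f.anchor >= 500)]
    return cfg, layout, truth, FeatureSet(isolated[:60], cfg.chromosome_lengths)


def wilcoxon_null_calibration(n_trials: int = 1000, seed: int = 0,
                              alpha: float = 0.05) -> float:
    """Fraction of mock-vs-mock resimulations with P < alpha."""
    cfg, layout, truth, feats = _calibration_layout(seed)
    params = default_factors()["Rad21"]
    mock = mock_condition()
    hits = 0
    for i in range(n_trials):
        occ = []
        for k in (0, 1):
            rng = child_rng(seed, "null-trial", str(2 * i + k))
            ip, inp = simulate_factor_tracks(layout, params, mock, cfg,
                                             rng=rng, truth=truth)
            enr = log2_enrichment(ip, inp, ENR)
            occ.append(feature_occupancy(enr, feats, 500).data["value"]
                       .to_numpy())
        _, p = signed_rank_p(occ[1] - occ[0])
        hits += p < alpha
    return hits / n_trials


def wilcoxon_depletion_power(seed: int = 0, reduction: float = 0.3,
                             n_enhancers: int = 60) -> float:
    """P-value for a planted enhancer amplitude reduction (default 30%,
    n = 60 enhancers, default noise)."""
    cfg = SimulationConfig(
        chromosome_lengths={"chr": 600_000}, n_origins=3,
        n_enhancers=n_enhancers, n_promoters=0, n_pres=0, n_random=0,
        n_transcripts=0, origin_min_separation=80_000,
        proximal_max_distance=15_000, distal_min_distance=30_000, seed=seed)
    layout, truth = generate_layout(cfg)
    enh = layout.by_class("enhancer")
    params = default_factors()["Rad21"]
    depleted = DepletionSpec("depl",
                             {"Rad21": {"enhancer": 1.0 - reduction}})
    occ = {}
    for cond, label in ((mock_condition(), "mock"), (depleted, "depl")):
        rng = child_rng(seed, "power", label)
        ip, inp = simulate_factor_tracks(layout, params, cond, cfg, rng=rng,
                                         truth=truth)
        enr = log2_enrichment(ip, inp, ENR)
        occ[label] = feature_occupancy(enr, enh, 500).data["value"].to_numpy()
    _, p = signed_rank_p(occ["depl"] - occ["mock"])
    return p


# ---------------------------------------------------------------------------
# replication-score ordering


def replication_ordering(n_reps: int = 100, seed: int = 0
                         ) -> Tuple[int, int, int]:
    """Count default-simulation replicates in which (a) high-SA promoters
    out-replicate all promoters and (b) extragenic enhancers out-replicate
    all enhancers (medians of early-replication scores)."""
    factors = default_factors()
    ok_pro = ok_enh = 0
    for i in range(n_reps):
        cfg = SimulationConfig(seed=seed + i)
        layout, truth = generate_layout(cfg)
        promoters = layout.by_class("promoter")
        ip, inp = simulate_factor_tracks(layout, factors["SA"],
                                         mock_condition(), cfg, truth=truth)
        sa = log2_enrichment(ip, inp, ENR)
        regions = call_enriched_regions(sa, 95.0, 300)
        cls = classify_high_sa(promoters, regions)
        edu_ip, edu_in = simulate_early_replication(layout, LAMBDA_REP, cfg)
        edu = log2_enrichment(edu_ip, edu_in, ENR)
        med_pro = replication_scores(promoters, edu).data["value"].median()
        high = cls.high_sa_subset(promoters)
        if len(high):
            med_high = replication_scores(high, edu).data["value"].median()
            ok_pro += med_high > med_pro
        enhancers = layout.by_class("enhancer")
        extragenic = extragenic_enhancers(enhancers,
                                          layout.by_class("transcript"))
        med_enh = replication_scores(enhancers, edu).data["value"].median()
        med_ext = replication_scores(extragenic, edu).data["value"].median()
        ok_enh += med_ext > med_enh
    return ok_pro, ok_enh, n_reps


# ---------------------------------------------------------------------------
# occupancy / meta-profile conservation


def conservation_error(seed: int = 0, n_features: int = 50) -> float:
    """Max |occupancy - mean of central profile bins| over isolated,
    bin-aligned plus-strand features on a random track."""
    from .track_io import Feature

    rng = child_rng(seed, "conservation")
    # profile_bin = 2 * bin_width and bin-boundary anchors make each
    # profile bin coincide with exactly two track bins, tiling the window
    w, window, flank, pb = 10, 500, 2000, 20
    length = 400_000
    track = BinnedTrack(w, {"chr": length},
                        {"chr": rng.normal(size=length // w)})
    spacing = length // (n_features + 2) // w * w
    # anchors on bin boundaries, far apart: no exclusion, exact alignment
    feats = [Feature("chr", (i + 1) * spacing, (i + 1) * spacing + window,
                     "+", "promoter", f"f{i}", (i + 1) * spacing)
             for i in range(n_features)]
    fs = FeatureSet(feats, {"chr": length})
    occ = feature_occupancy(track, fs, window).data.set_index("feature")
    worst = 0.0
    for f in feats:
        prof = meta_profile(track, FeatureSet([f], {"chr": length}), flank, pb)
        # profile bins whose intervals tile the occupancy window exactly
        central = ((prof.offsets - pb // 2 >= -(window // 2))
                   & (prof.offsets + (pb - pb // 2) <= window - window // 2))
        got = float(prof.values[central].mean())
        worst = max(worst, abs(got - float(occ.loc[f.name, "value"])))
    return worst


# ---------------------------------------------------------------------------
# exact-statistic oracle agreement


def wilcoxon_oracle_agreement(n_cases: int = 40, seed: int = 0,
                              max_n: int = 10) -> Tuple[int, int]:
    """Exact signed-rank P vs full 2**n sign enumeration on random data."""
    rng = child_rng(seed, "wilcoxon-oracle")
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(3, max_n + 1))
        # distinct magnitudes, random signs
        mags = np.sort(rng.uniform(0.5, 10.0, size=n))
        d = mags * rng.choice([-1.0, 1.0], size=n)
        _, p = signed_rank_p(d)
        p_ref = wilcoxon_exact_enumeration(d)
        agree += abs(p - p_ref) < 1e-12
    return agree, n_cases


def fisher_oracle_agreement(max_margin: int = 30) -> Tuple[int, int]:
    """Fisher two-sided P vs exact enumeration on every 2x2 table whose
    margins are all <= max_margin."""
    agree = total = 0
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            n_tot = r1 + r2
            if n_tot == 0:
                continue
            for c1 in range(max(0, n_tot - max_margin),
                            min(n_tot, max_margin) + 1):
                lo, hi = max(0, c1 - r2), min(r1, c1)
                for a in range(lo, hi + 1):
                    table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                    p = float(stats.fisher_exact(table)[1])
                    p_ref = fisher_exact_enumeration(*table[0], *table[1])
                    total += 1
                    agree += abs(p - p_ref) <= 1e-9
    return agree, total
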