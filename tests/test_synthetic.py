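"""Synthetic layouts and tracks: determinism, construction rules, noise."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from cohesin_occupancy.enrichment import EnrichmentParams, log2_enrichment
from cohesin_occupancy.synthetic import (DepletionSpec, FactorParams,
                                         LayoutError, SimulationConfig,
                                         child_rng, default_factors,
                                         generate_layout, mock_condition,
                                         planted_amplitude,
                                         sa_depletion_condition,
                                         simulate_early_replication,
                                         simulate_factor_tracks,
                                         truth_occupancy, write_layout)
from cohesin_occupancy.track_io import read_bed, read_chrom_sizes


class TestConfigValidation:
    def test_rejects_bad_fractions_and_distances(self):
        with pytest.raises(ValueError):
            SimulationConfig(promoter_proximal_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(proximal_max_distance=50_000,
                             distal_min_distance=40_000)
        with pytest.raises(ValueError):
            SimulationConfig(noise_dispersion=-0.1)

    def test_factor_params_validation(self):
        with pytest.raises(ValueError):
            FactorParams("x", peak_sd=0.0)
        with pytest.raises(ValueError):
            FactorParams("x", stoichiometry_distal=1.5)
        with pytest.raises(ValueError):
            DepletionSpec("d", {"SA": {"enhancer": -1.0}})


class TestLayout:
    def test_counts_match_config(self, small_config, small_layout):
        layout, truth = small_layout
        counts = truth["class"].value_counts()
        assert counts["origin"] == small_config.n_origins
        assert counts["enhancer"] == small_config.n_enhancers
        assert counts["promoter"] == small_config.n_promoters
        assert counts["PRE"] == small_config.n_pres
        assert counts["random"] == small_config.n_random
        assert counts["transcript"] == small_config.n_transcripts

    def test_no_promoters_when_count_zero(self, small_config):
        cfg = dataclasses.replace(small_config, n_promoters=0)
        layout, truth = generate_layout(cfg)
        assert len(layout.by_class("promoter")) == 0

    def test_all_proximal_when_fraction_one(self, small_config):
        cfg = dataclasses.replace(small_config,
                                  promoter_proximal_fraction=1.0,
                                  proximal_max_distance=5_000)
        _, truth = generate_layout(cfg)
        pro = truth[truth["class"] == "promoter"]
        assert (pro["origin_distance"] <= 5_000).all()

    def test_distance_rules_hold(self, small_config, small_layout):
        _, truth = small_layout
        cfg = small_config
        pre = truth[truth["class"] == "PRE"]
        assert (pre["origin_distance"] >= cfg.distal_min_distance).all()
        tx = truth[truth["class"] == "transcript"]
        assert (tx["origin_distance"]
                >= cfg.transcript_min_origin_distance).all()
        n_prox = (truth[truth["class"] == "promoter"]["origin_distance"]
                  <= cfg.proximal_max_distance).sum()
        assert n_prox == round(cfg.promoter_proximal_fraction
                               * cfg.n_promoters)

    def test_origin_minimum_separation(self, small_config, small_layout):
        _, truth = small_layout
        ori = truth[truth["class"] == "origin"]
        for chrom, grp in ori.groupby("chrom"):
            pos = np.sort(grp["anchor"].to_numpy())
            assert (np.diff(pos) >= small_config.origin_min_separation).all()

    def test_truth_distances_match_brute_force(self, small_layout):
        layout, truth = small_layout
        origins = [(f.chrom, f.anchor) for f in layout.by_class("origin")]
        for _, row in truth.sample(50, random_state=0).iterrows():
            d = min((abs(row["anchor"] - a)
                     for c, a in origins if c == row["chrom"]),
                    default=2**62)
            assert row["origin_distance"] == d

    def test_determinism(self, small_config):
        l1, t1 = generate_layout(small_config)
        l2, t2 = generate_layout(small_config)
        pd.testing.assert_frame_equal(t1, t2)
        assert [(f.chrom, f.start, f.end, f.strand) for f in l1] == \
            [(f.chrom, f.start, f.end, f.strand) for f in l2]

    def test_infeasible_layout_fails_loudly(self):
        cfg = SimulationConfig(
            chromosome_lengths={"c": 150_000}, n_origins=30,
            origin_min_separation=100_000, proximal_max_distance=10_000,
            distal_min_distance=30_000, n_transcripts=0)
        with pytest.raises(LayoutError):
            generate_layout(cfg)


class TestTracks:
    def test_noise_free_matches_direct_summation_oracle(self, small_config,
                                                        small_layout):
        """Independent per-bin oracle: loop over every feature and every
        bin, summing Gaussian contributions."""
        layout, truth = small_layout
        cfg = small_config
        params = default_factors()["SA"]
        cond = sa_depletion_condition()
        ip, inp = simulate_factor_tracks(layout, params, cond, cfg,
                                         noise_free=True, truth=truth)
        mu = {c: np.log2(ip.values[c] / inp.values[c])
              for c in cfg.chromosome_lengths}
        tt = truth.set_index("feature")
        chrom = "chrA"
        expected = np.zeros(mu[chrom].size) + params.baseline
        centers = np.arange(expected.size) * cfg.bin_width + cfg.bin_width / 2
        for f in layout:
            if f.chrom != chrom:
                continue
            d = tt.loc[f.name, "origin_distance"]
            amp = params.class_amplitude.get(f.class_label, 0.0)
            amp *= cond.factor_multiplier(
                params.name, f.class_label, d <= cfg.proximal_max_distance)
            amp *= math.exp(-d / params.origin_decay_length)
            if f.class_label == "promoter" and d > cfg.proximal_max_distance:
                amp *= params.stoichiometry_distal
            sign = -1 if f.strand == "-" else 1
            peak = f.anchor + sign * params.peak_offset
            expected += amp * np.exp(-((centers - peak) ** 2)
                                     / (2 * params.peak_sd ** 2))
        np.testing.assert_allclose(mu[chrom], expected, atol=1e-9)

    def test_zero_amplitudes_noise_free_is_baseline(self, small_config,
                                                    small_layout):
        layout, truth = small_layout
        params = FactorParams("null", baseline=0.25, class_amplitude={})
        ip, inp = simulate_factor_tracks(layout, params, mock_condition(),
                                         small_config, noise_free=True,
                                         truth=truth)
        enr = log2_enrichment(ip, inp, EnrichmentParams(0.0, "none"))
        np.testing.assert_allclose(enr.all_values(), 0.25, atol=1e-12)

    def test_sampled_mean_tracks_expectation(self, small_config, small_layout):
        """Mean of >=10^4 background IP bins within 3 SE of the planted
        mean read depth."""
        layout, truth = small_layout
        cfg = small_config
        params = FactorParams("flat", class_amplitude={})
        ip, _ = simulate_factor_tracks(layout, params, mock_condition(), cfg,
                                       truth=truth,
                                       rng=child_rng(5, "mean-check"))
        counts = ip.all_values()
        assert counts.size >= 10_000
        m = cfg.read_depth
        se = math.sqrt((m + cfg.noise_dispersion * m * m) / counts.size)
        assert abs(counts.mean() - m) <= 3 * se

    def test_track_determinism(self, small_config, small_layout):
        layout, truth = small_layout
        params = default_factors()["Rad21"]
        pair1 = simulate_factor_tracks(layout, params, mock_condition(),
                                       small_config, truth=truth)
        pair2 = simulate_factor_tracks(layout, params, mock_condition(),
                                       small_config, truth=truth)
        for t1, t2 in zip(pair1, pair2):
            for c in t1.chrom_lengths:
                np.testing.assert_array_equal(t1.values[c], t2.values[c])

    def test_poisson_limit_at_zero_dispersion(self, small_config,
                                              small_layout):
        layout, truth = small_layout
        cfg = dataclasses.replace(small_config, noise_dispersion=0.0)
        params = FactorParams("flat", class_amplitude={})
        ip, _ = simulate_factor_tracks(layout, params, mock_condition(), cfg,
                                       truth=truth,
                                       rng=child_rng(5, "poisson"))
        counts = ip.all_values()
        # Poisson: variance ~= mean
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.05)


class TestTruthOccupancy:
    def test_zero_stoichiometry_zeroes_distal_promoters(self, small_config,
                                                        small_layout):
        _, truth = small_layout
        factors = {"SA": default_factors()["SA"]}
        full = truth_occupancy(truth, factors, [mock_condition()],
                               small_config)
        pro = full[full["class"] == "promoter"]
        distal = pro[pro["origin_distance"]
                     > small_config.proximal_max_distance]
        assert (distal["SA:mock"] == 0.0).all()
        proximal = pro[pro["origin_distance"]
                       <= small_config.proximal_max_distance]
        assert (proximal["SA:mock"] > 0.0).all()

    def test_depletion_multiplier_scales_amplitude(self, small_config):
        params = default_factors()["Rad21"]
        depl = DepletionSpec("d", {"Rad21": {"enhancer": 0.5}})
        base = planted_amplitude("enhancer", 1_000, params, mock_condition(),
                                 small_config)
        reduced = planted_amplitude("enhancer", 1_000, params, depl,
                                    small_config)
        assert reduced == pytest.approx(0.5 * base)

    def test_proximal_distal_promoter_keys_take_precedence(self, small_config):
        params = default_factors()["Rad21"]
        depl = DepletionSpec("d", {"Rad21": {"promoter": 0.5,
                                             "promoter_distal": 2.0}})
        prox = planted_amplitude("promoter", 1_000, params, depl, small_config)
        dist = planted_amplitude("promoter", 100_000, params, depl,
                                 small_config)
        base_prox = planted_amplitude("promoter", 1_000, params,
                                      mock_condition(), small_config)
        base_dist = planted_amplitude("promoter", 100_000, params,
                                      mock_condition(), small_config)
        assert prox == pytest.approx(0.5 * base_prox)
        assert dist == pytest.approx(2.0 * base_dist)


class TestEarlyReplication:
    def test_monotone_decay_and_origin_maximum(self, small_config,
                                               small_layout):
        layout, truth = small_layout
        ip, inp = simulate_early_replication(layout, 15_000.0, small_config,
                                             noise_free=True)
        enr = {c: np.log2(ip.values[c] / inp.values[c])
               for c in small_config.chromosome_lengths}
        origins = [f for f in layout.by_class("origin") if f.chrom == "chrA"]
        vec = enr["chrA"]
        w = small_config.bin_width
        # origin-center bins are (tied) maxima
        ori_bins = [f.anchor // w for f in origins]
        assert max(vec[b] for b in ori_bins) == pytest.approx(vec.max(),
                                                              abs=1e-6)
        # pairwise monotonicity in origin distance
        centers = np.arange(vec.size) * w + w / 2
        pts = np.array([f.anchor for f in origins])
        d = np.min(np.abs(centers[:, None] - pts[None, :]), axis=1)
        order = np.argsort(d)
        diffs = np.diff(vec[order])
        assert (diffs <= 1e-9).all()

    def test_infinite_decay_gives_flat_track(self, small_config, small_layout):
        layout, _ = small_layout
        ip, inp = simulate_early_replication(layout, math.inf, small_config,
                                             amplitude=2.0, noise_free=True)
        vec = np.log2(ip.values["chrA"] / inp.values["chrA"])
        np.testing.assert_allclose(vec, 2.0, atol=1e-12)

    def test_invalid_decay_rejected(self, small_config, small_layout):
        layout, _ = small_layout
        with pytest.raises(ValueError):
            simulate_early_replication(layout, 0.0, small_config)


def test_write_layout_round_trips_through_bed(tmp_path, small_config,
                                              small_layout):
    layout, truth = small_layout
    paths = write_layout(tmp_path / "run", layout, truth, small_config)
    sizes = read_chrom_sizes(paths["chrom_sizes"])
    assert sizes == small_config.chromosome_lengths
    proms = read_bed(paths["bed:promoter"], "promoter", sizes)
    orig = layout.by_class("promoter")
    assert len(proms) == len(orig)
    # strand-aware TSS anchors survive the BED round trip
    assert [f.anchor for f in proms] == [f.anchor for f in orig]
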