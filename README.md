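# cohesin-occupancy

A ChIP-seq feature-occupancy pipeline for studying how cohesin subunits
(SA/STAG, Rad21, SMC1), the loader Nipped-B (NIPBL) and associated
factors distribute over functional genomic features — promoters,
enhancers, Polycomb response elements (PREs) and early DNA replication
origins — and how that distribution shifts under depletion conditions.

The package is aimed at regulatory-genomics analysts who start from
binned coverage (bedGraph) and BED feature files and want reproducible,
tested implementations of the standard quantification steps:

- **log2 enrichment**: `log2(((IP_b + c)/S_ip) / ((input_b + c)/S_in))`
  per fixed-width bin, with a pseudocount *c* and optional total-count
  depth normalization.
- **Enrichment-region calling**: maximal runs of bins at or above a
  genome-wide percentile threshold (default the 95th), kept when they
  span at least a minimum length (default 300 bp).
- **Feature occupancy**: mean enrichment over a 500-bp window centered
  on each feature's anchor (the TSS for promoters, strand-aware;
  interval midpoints otherwise).
- **Meta-profiles**: strand-oriented average enrichment by offset from
  the anchor, with overlap exclusion, plus peak-offset localization.
- **Classification**: "high-SA" promoters (window overlaps a called SA
  region), early-replication proximity scores from an EdU-style track,
  and extragenic enhancers (≥ 500 bp outside transcribed regions).
- **Statistics**: paired Wilcoxon signed-rank shifts between conditions,
  through-origin subunit-stoichiometry slopes
  (`k = Σ a_i b_i / Σ a_i²`), Fisher's exact viability tests and
  Welch's t-test for genetic-interaction counts.

Because real depth-matched track pairs are bulky, the package ships a
**synthetic-genome simulator** that plants the signal structure this
analysis assumes — origins with clustered enhancers, a mostly
origin-distal promoter population, per-factor peak offsets and
origin-distance decay, subproportional SMC1 at distal promoters,
negative-binomial read noise — together with ground-truth tables, so
every stage is verified end to end by parameter recovery.

## Worked example

```python
from cohesin_occupancy import (
    SimulationConfig, generate_layout, simulate_factor_tracks,
    default_factors, mock_condition, EnrichmentParams, log2_enrichment,
    call_enriched_regions, classify_high_sa, meta_profile, peak_offset)

cfg = SimulationConfig(seed=3)                       # 2 x 2 Mb genome
layout, truth = generate_layout(cfg)
factors = default_factors()

sa_ip, sa_in = simulate_factor_tracks(layout, factors["SA"],
                                      mock_condition(), cfg)
sa = log2_enrichment(sa_ip, sa_in, EnrichmentParams(1.0, "none"))

regions = call_enriched_regions(sa, percentile=95, min_length=300)
promoters = layout.by_class("promoter")
cls = classify_high_sa(promoters, regions)
print(len(regions), round(regions.threshold, 3), cls.n_high, cls.n_total)

rad_ip, rad_in = simulate_factor_tracks(layout, factors["Rad21"],
                                        mock_condition(), cfg)
rad = log2_enrichment(rad_ip, rad_in, EnrichmentParams(1.0, "none"))
prof = meta_profile(rad, promoters, flank=2000, profile_bin=10)
print(prof.n_used, peak_offset(prof))
```

This prints

```
54 0.788 27 300
151 -70.0
```

meaning: 54 SA enrichment regions were called at the genome-wide 95th
percentile threshold of 0.788 log2 units; 27 of 300 promoters (9%)
overlap one and are classified high-SA (the planted layout makes 15% of
promoters origin-proximal, and only those carry SA); and the Rad21
promoter meta-profile over the 151 promoters surviving overlap/edge
exclusion peaks 70 bp upstream of the TSS — exactly where the simulator
planted it.

The same stages run from the shell via the `cohesin-occupancy` console
script (`enrich`, `call-regions`, `occupancy`, `metaprofile`,
`classify`, `compare`, `fisher`, and `pipeline run config.yaml` for an
orchestrated, manifest-checked run).

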