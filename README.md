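# scaleofeffect

Multi-scale buffer analysis of landscape anthropisation effects on mosquito
communities: estimating the **scale of effect** of forest, urban and
agricultural cover on community responses, with bootstrap uncertainty and
standardized effect-size comparison.

## The problem

Landscape variables influence species abundance and diversity, but only when
measured at the right spatial extent around the sampling sites — the *scale
of effect*. For mosquitoes this matters doubly: larvae experience a few
meters of habitat while adults move hundreds of meters daily, and the three
main anthropisation gradients (urbanisation, deforestation, agricultural
development) need not act at the same scale. Fixing one buffer size a
priori risks missing real effects entirely.

This package implements the multi-scale workflow for site-based community
surveys:

1. **Cover profiling.** Land cover is a categorical raster over the classes
   `{forest, urban, agriculture, other}`. Around each site, class
   proportions are measured inside concentric circular buffers over a
   radius series (canonically 150–5000 m in 10 m steps, 485 buffers; a cell
   belongs to a buffer iff its center lies within the radius).
2. **Community responses.** From a `site × taxon × session` count table:
   Shannon diversity H = −Σ pᵢ ln pᵢ per site, and per-taxon abundance =
   total individuals / sampling effort, restricted to the common taxa whose
   cumulative share of individuals reaches 97%.
3. **Scale selection.** For each component × response pair, a simple linear
   regression of the response on the component's cover is fitted at every
   radius; the scale of effect is the radius maximizing R² (ties → smallest
   radius).
4. **Bootstrap uncertainty.** Sites are resampled with replacement
   (B = 1000 by default), the full R² profile recomputed per resample, and
   the distribution of selected scales summarized by its mode and central
   interval.
5. **Effect sizes.** Each response is regressed on all three components
   together, everything z-scored, with components at their selected scales
   and, for comparison, all at an a priori 400 m (the median daily movement
   distance of mosquitoes). Coefficients are reported as standardized
   betas ± SE with t-test p-values and significance codes.

A first-class synthetic-data module generates landscapes (thresholded
smooth random fields), sites, and overdispersed multi-taxon communities
with *planted* scales and effects, so the whole pipeline is validated by
parameter recovery without any external GIS or field data.

## Worked example

```python
from scaleofeffect import (single_component_config, simulate_dataset,
                           scale_profile, bootstrap_scale)

# a landscape with a forest effect planted at a 1000 m radius, noise at
# one third of the signal SD, 16 sites
config = single_component_config("forest", true_scale=1000.0, beta=1.0, snr=3.0)
grid, sites, profile, sim = simulate_dataset(config, seed=42)

sp = scale_profile(profile, sim.response, "forest")
dist = bootstrap_scale(profile, sim.response, "forest", B=1000, seed=42)
print(f"selected scale of effect: {sp.selected_scale:.0f} m")
print(f"max R2: {sp.r2.max():.3f}")
lo, hi = dist.central_interval()
print(f"bootstrap mode: {dist.mode:.0f} m, 95% interval [{lo:.0f}, {hi:.0f}] m")
```

prints

```
selected scale of effect: 1000 m
max R2: 0.917
bootstrap mode: 950 m, 95% interval [900, 1150] m
```

— the selection lands on the planted 1000 m radius, the strongest radius
explains ~92% of response variance, and the bootstrap concentrates within
a few 50 m grid steps of it. Effect-size recovery over replicated
datasets, with planted standardized betas (forest −0.5, urban +0.6,
agriculture 0):

```python
from scaleofeffect import SyntheticConfig, recovery_experiment
report = recovery_experiment(SyntheticConfig(), 50, seed=42)
print(report.mean_betas().round(3))
```

```
agriculture    0.009
forest        -0.479
urban          0.623
```

The full pipeline (grid + sites + counts files → profiles, selected
scales, bootstrap distributions, effect tables, manifest) runs from a YAML
config:

```bash
scaleofeffect simulate --seed 1 --out data/
scaleofeffect run --config run.yaml --seed 1 --out results/
```

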