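# habsel

Use/availability habitat-selection analysis for territory-mapping surveys:
Manly's alpha and Chesson's electivity index with accelerated-bootstrap
significance, plus the landscape-change metrics (fragmentation, Shannon
diversity, infrastructure trends) needed to interpret selection in a
changing agricultural landscape.

## Who this is for

Field ecologists holding bird (or other wildlife) locations mapped inside
survey squares together with categorical land-cover maps per square and
year, who want to know which habitat types the animals prefer or avoid,
whether that selection is statistically defensible, and how the landscape
itself changed over the survey years.  The built-in defaults mirror grey
partridge surveys near a growing city: squares of 618 m side, 100 m
(≈3.14 ha) circular plots around each location, winter coveys (>2 birds)
and spring territories, a rough land-cover scale (arable, meadow,
vineyard, forest, hedgerow, water, roads, settlements, …) and a fine
within-field scale (winter grain, harvested field, fallow/green manures,
field paths, hedges with a "super hedge" quality classification, …).

## The statistic

For habitat type i with used proportion r_i and available proportion n_i
over the m available types:

    α_i = (r_i / n_i) / Σ_j (r_j / n_j)          (Manly's alpha, Σα = 1)
    ε_i = (m·α_i − 1) / ((m − 2)·α_i + 1)        (Chesson's electivity)

ε ∈ [−1, 1]; 0 means use proportional to availability, and values are
comparable between units facing different numbers of available types.
Per habitat, the mean of unit-level ε gets a BCa bootstrap CI (default
1500 resamples, 95%); endpoints sharing a sign mean significant
preference/avoidance, an interval containing zero is not significant, and
habitats backed by fewer than 7 units are not tested.  Details, design
choices and caveats: [docs/methods.md](docs/methods.md).

## Worked example

A unit whose plots contain 50/30/20% of habitats a/b/c in a landscape
offering 20/30/50%:

```python
from habsel import manly_alpha, chesson_epsilon

alpha = manly_alpha({"a": 0.5, "b": 0.3, "c": 0.2},
                    {"a": 0.2, "b": 0.3, "c": 0.5})
print(alpha.round(4).to_dict())
print(chesson_epsilon(alpha).round(4).to_dict())
```

prints

```
{'a': 0.641, 'b': 0.2564, 'c': 0.1026}
{'a': 0.5625, 'b': -0.1837, 'c': -0.6279}
```

Habitat a is used at 2.5× its availability (α = 0.641 of the total
selection, ε = +0.56: preferred); c is used at 0.4× its availability
(ε = −0.63: avoided).  The full pipeline — synthetic landscape with known
truth, circular-plot compositions, per-square availability, bootstrap
significance — is in [examples/synthetic_pipeline.py](examples/synthetic_pipeline.py);
the other scripts under `examples/` each demonstrate one capability
(bootstrap significance, multi-year landscape change) and print a short
interpretation of their numbers.

## Command line

For shell-driven runs the same pipeline is exposed as a thin CLI:

```bash
habsel simulate --scenario fixture --seed 3 --outdir data/
habsel validate --observations data/observations.csv --maps data/maps
habsel analyze  --observations data/observations.csv --maps data/maps \
                --level individual --seed 3 --outdir out/
habsel report   --summary out/electivity_summary.csv --out out/electivity.png
```

`analyze` writes five tidy CSVs (per-unit electivities, per-habitat
bootstrap summary, change tables, diversity, distance summary) and a
`run_metadata.json` whose config hash + seed fully determine every number.

## Data formats

Observations: CSV with `obs_id, square_id, x, y, year, season, unit_kind,
group_size[, unit_id]` (projected metric coordinates).  Patch maps: either
a directory of Esri ASCII grids with JSON legends (one file per square and
year) or a GeoJSON FeatureCollection of labelled polygons with
`square_id`, `year`, `scale`, `habitat` properties.  All readers/writers
round-trip exactly; see `habsel.io`.
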