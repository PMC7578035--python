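# transbound

Classify exploited marine species as **transboundary** or **discrete** per
Exclusive Economic Zone (EEZ) from gridded presence data and an EEZ adjacency
graph, categorize their catch trends, and account catch and ex-vessel revenue
by stock class, country, and UN sub-region.

The pipeline has six stages:

1. **synthetic world** (`transbound.synth`) — a fully synthetic test bed:
   an EEZ mosaic with known adjacency, species ranges with controllable
   per-region share fractions, four presence sources with a tunable agreement
   rate, catch series constructed to realize a chosen trend category, and
   price/CPI tables — all with recorded ground truth.
2. **spatial model** (`transbound.spatial`) — a 0.5° lon/lat grid with
   latitude-corrected cell areas, center-point cell-to-region assignment, and
   the neighboring-EEZ graph with country/territory collapsing rules
   (same-country sub-regions and same-nation territories are unusable edges;
   associated states inherit their parent country before edge evaluation).
3. **presence consensus** (`transbound.consensus`) — a cell belongs to a
   species' range only when occurrence, both distribution models and the
   catch layer all agree **and** the cell recorded positive catch in at least
   one year of the 2005–2014 window.
4. **classification** (`transbound.classifier`) — for every usable
   neighboring pair, each region's *Area Index* is its share of the pair's
   joint range area; a pair passes when both shares strictly exceed the
   threshold (default 25%). Stocks with a passing incident pair are
   transboundary; remaining stocks of a transboundary species are
   *excluded stocks*; species with no passing pair anywhere are discrete.
5. **catch trends** (`transbound.trends`) — per-year categories
   A (increasing) / B (constant) / C (decreasing) with precedence B→A→C,
   eligibility rules (≥10 data years in 1951–2014, ≥5 consecutive), and the
   predominant category over 2005–2014.
6. **accounting** (`transbound.accounting`) — revenue = catch × ex-vessel
   price (2010 real USD) standardized to 2019 USD via CPI; window means;
   partition into transboundary / excluded / discrete accounts; country and
   UN sub-region rollups with per-km² weighting.

## CLI

```bash
# generate a synthetic world with ground truth
synth-world --seed 1 --n-regions 6 --n-species 10 --agreement 1.0 --out world/
# (equivalently: transbound synth ...)

# full pipeline from a YAML config
transbound run --config config.yaml

# individual stages
transbound classify --world world/ --threshold 0.25 --area-weighting km2 --out cls.csv
transbound trends --catch world/catch.csv --window 2005:2014 --out trends.csv
transbound account --world world/ --classification cls.csv --target-usd-year 2019 --out accounts/
```

A minimal `config.yaml`:

```yaml
out_dir: run_out
seed: 1
n_regions: 6
n_species: 10
threshold: 0.25
window: [2005, 2014]
sweep_thresholds: [0.05, 0.1, 0.25, 0.4, 0.5]
```

`transbound run` writes every stage artifact (cell assignment, neighbor
edges, consensus, classification, Area Indices, trend assessments, revenue,
accounts, a plain-text summary) plus `manifest.json` with the config, input
checksums and per-stage row counts; reruns with the same config are bitwise
identical.

## Data formats

All inputs/outputs are plain text: regions as GeoJSON (WGS84, properties
`region_id, name, country_id, country_name, un_subregion, territory_class,
parent_country_for_grouping, area_km2`); presence layers
(`species_id, source, cell_id`), catch (`species_id, region_id, year,
tonnes`), spatialized catch (`species_id, cell_id, year, tonnes`), prices
(`species_id, country_id, year, price`), CPI (`year[, month], cpi`) as CSV;
ground truth and manifests as JSON.
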