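# ldscreen

High-content screening pipeline for cellular lipid-droplet (LD) formation:
synthetic two-channel fluorescence plates with per-cell ground truth,
nuclei/cytoplasm/droplet segmentation, per-well quantification, and
plate-level hit calling with dose–response and uptake-kinetics analysis.

## The problem

Cells store excess fatty acids as neutral lipids in lipid droplets. A
classic cell-based screen for molecules that modulate lipid storage works
like this: cells are first depleted of droplets in delipidated serum, then
loaded with oleic acid to drive droplet biogenesis; each well is stained
with DAPI (nuclei) and a neutral-lipid dye (droplets) and imaged. Per well
the assay reports the **mean number of LDs per cell**; the **number of
nuclei per field** is a surrogate for cytotoxicity. An extract or compound
is called a hit when its duplicate-averaged metric falls outside the
plate's *normal range*,

```
normal range = mean ± k · SD   over the plate's extract-level values (k = 1)
```

with LD-increase above, LD-decrease below, and cytotoxicity below the
nuclei-per-field range. Percent inhibition of droplet formation is measured
against the loaded (0%) and delipidated (100%) controls, and fatty-acid
uptake time courses follow a saturating exponential
`I(t) = I_max (1 − e^(−t/τ))` with plateau at `3τ`.

`ldscreen` implements this pipeline end-to-end and ships a seeded simulator
whose scenes come with full ground truth (every nucleus, territory and
droplet), so every stage — spot detection, per-cell counting, hit calling —
is validated against known answers. It is aimed at people building or
stress-testing high-content image-analysis pipelines.

## Worked example

Simulate one 96-well screening plate (42 extracts in duplicate, 6 inactive
extract + 6 triacsin-C control wells, with planted actives: one 3× LD
increaser, two 0.4× decreasers, two cytotoxic extracts), segment and
quantify every well, and call hits:

```python
from ldscreen import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=7, out_dir="demo_out"))
print(report["hit_counts"])
print(report["hit_rate_increase_pct"], report["hit_rate_decrease_pct"])
print(round(report["qc"]["z_prime"], 2))
```

prints

```
{'n_ld_increase': 1, 'n_ld_decrease': 2, 'n_cytotoxic': 2, 'n_cytotoxic_and_ld_increase': 0, 'n_cytotoxic_and_ld_decrease': 0}
2 5
0.72
```

— the three planted LD modulators and both cytotoxic extracts are recovered
with no false positives (1/42 ≈ 2% increase rate, 2/42 ≈ 5% decrease rate),
and the triacsin-C vs loaded-control separation gives an excellent-quality
Z′ ≈ 0.72. `demo_out/` contains the plate map, per-well metrics, per-extract
calls with audit columns, the ground truth, and `report.json` embedding the
exact config and seed (reruns are bit-identical).

The same machinery is scriptable from the shell:

```sh
ldscreen simulate --scenario primary-screen --seed 7 --out plate/
ldscreen quantify --images plate/ --out quant/
ldscreen screen --wells quant/well_metrics.csv --plate-map plate/plate_map.csv --k 1 --out calls/
ldscreen dose --table doses.csv --baseline 3.5 --positive 35
ldscreen kinetics --table uptake.csv
ldscreen run --seed 7 --out demo_out/
```

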