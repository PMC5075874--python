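# wormchip

Automated analysis of *C. elegans* killing assays performed in microfluidic
chambers.

A killing assay tracks how many worms survive exposure to a pathogen (for
example *Pseudomonas aeruginosa* PA14) over several days. Performed in a
shallow micro-pillar chamber and imaged hourly in bright field, the assay can
be scored entirely by software: worms appear as dark elongated bodies on a
light background, a dead worm's opacity collapses within hours as the cadaver
degrades, and — because worms cannot leave the chamber — the survival curve
needs no censoring. `wormchip` implements that scoring pipeline for people
who run such assays (or want to prototype one), plus a ground-truthed
synthetic scene generator so every stage can be validated without a
microscope.

## What it computes

- **Segmentation** — worm-pixel masks via local-background thresholding,
  8-connected components, and a single-worm **area model**: with 30–35 worms
  per chamber single-worm components dominate, so the single-worm area is the
  dominant mode of the component-area distribution, and a component holding
  area *A* is counted as `round(A / single_worm_area)` worms.
- **Separation of touching worms** — the core algorithm. The chamber is too
  shallow for worms to cross, so a multi-worm component is a planar
  arrangement of touching bodies. Narrow regions (local width ≤ 1.3× a
  single worm's half-width, from the distance transform) are body parts;
  thicker regions are junctions. The signed **turn angle** along the
  component boundary flags turns too sharp to come from a worm silhouette —
  these are worm–worm contact notches, and connections across them are
  prohibited. Remaining part endpoints are paired by tangent, alignment and
  body-width continuity; end-to-end chains that turn angles cannot resolve
  are cut into individuals using the mean isolated-worm length as a ruler
  (snapping cuts to width constrictions, which mark tip-to-tip contacts).
- **Per-worm phenotypes** — opacity (mean darkness), viability
  (`dead` when opacity ≤ neighborhood mean + image-darkness SD), total
  background-subtracted fluorescence (e.g. an *irg-1::GFP* reporter), and
  motility: the fraction of a worm's pixels in the later of two ~1-s-spaced
  frames not covered by worm pixels in the earlier frame.
- **Survival statistics** — chip curves S(t) = alive(t)/n₀ with binomial
  SE and isotonic correction of count jitter; the Kaplan–Meier
  product-limit estimator S(t) = ∏(1 − dᵢ/nᵢ) with Greenwood SE for
  plate-style data with lost (censored) worms; median survival, pointwise
  comparison and log-rank tests.
- **Synthetic scenes** — parametric worms (damped-sinusoid midlines, tapered
  tube bodies) placed with side/end contacts but never overlapping, a
  hexagonal pillar lattice, post-mortem opacity decay, per-worm fluorescence
  and motility pairs — with exact per-pixel ground truth.

## Worked example

```bash
python examples/02_separate_cluster.py
```

```
6 components; single-worm area 981 px, length ruler 97 px
cluster component: 2759 px, expected 3 worms -> 3 instances (success=True)
  instance 1 [resolved]: 889 px, matches true worm 1 at IoU 0.98
  instance 2 [resolved]: 806 px, matches true worm 3 at IoU 1.00
  instance 3 [resolved]: 1064 px, matches true worm 2 at IoU 0.98
```

A synthetic side-touching cluster of three worms is masked, counted from the
area model (2759 px ≈ 3 × 981 px), and separated; each recovered instance
overlaps its ground-truth worm at IoU ≥ 0.98. `examples/` holds one script
per capability: scene simulation, cluster separation, survival curves, and a
full simulated assay analyzed end to end.

## Command line

A thin CLI wraps the library:

```bash
wormchip simulate scene.yaml --seed 4 --out sim/      # render a scene/assay
wormchip run frames/ --out results/ --seed 1          # full pipeline
wormchip segment frames/ --out results/               # masks + components only
wormchip survival records.csv --out curve.csv         # Kaplan-Meier from CSV
```

Input frames are grayscale TIFF/PNG named
`<chamber>_<bf|fl>_t<hours>_p<0|1>.tif`; `--pattern` accepts any regex with
named groups `chamber`, `channel`, `time`, `pair` for other layouts. Outputs
are CSV tables (measurements, survival), 16-bit label-mask TIFFs and a JSON
run manifest recording the seed and config hash; reruns under the same seed
and config are byte-identical.

## Layout

```
src/wormchip/
  synthetic.py     ground-truthed scene and time-lapse generator
  io.py            frame loading, result tables, label masks, manifest
  segmentation.py  masking, components, area model
  separation.py    turn angles, body parts, junction resolution, chains
  phenotyping.py   viability, time of death, fluorescence, motility, CDFs
  survival.py      chip and Kaplan-Meier curves, comparisons
  pipeline.py      end-to-end orchestration
  cli.py           thin command-line layer
  benchmarks.py    reproducible synthetic benchmarks
docs/methods.md    model, parameters, design decisions, limitations
examples/          one narrative script per capability
```
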