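# aznano

Nanoscale co-organization analysis of presynaptic proteins from
single-molecule localization microscopy (DNA Exchange-PAINT) data.

Active zones cluster voltage-gated Ca²⁺ channels (CaV2.1) and concentrate the
vesicle-priming protein Munc13-1 into nanoclusters tens of nanometers across.
Whether these two machineries occupy the same subsynaptic sites is a
quantitative question about point patterns: given per-target localization
tables for a synapse, how clustered is each protein, how enriched is one
protein around the other's nanoclusters relative to chance, and do nanocluster
boundaries overlap? `aznano` implements that analysis chain for localization
tables (CSV/HDF5), from raw quality filtering to population statistics, plus a
synthetic-data generator that plants known architectures so every stage is
verifiable, and a STED side-view line-profile module for axial protein
distributions.

## Analysis chain

1. **Preprocessing** — quality filters (PSF-fit σ outside (0.3, 1.6) px,
   localization error > 20 nm, photons above the modal histogram bin),
   redundant cross-correlation drift correction (1000-frame segments),
   degree-2 polynomial chromatic correction from bead control points, residual
   inter-target offset correction by image cross-correlation, and temporal
   linking of blinking events (0.3 px radius, ≤ 5 dark frames).
2. **Synapse selection** — DBSCAN on the scaffold targets (ε = 48 nm,
   minPts = 10, ≥ 75 localizations), rejection of nonspecific-binding clusters
   by frame statistics (frame SD outside (2500, 11000) or mean frame outside
   μ ± 2σ of a gaussian fit across clusters), en-face selection by the
   smoothed-scaffold aspect ratio (≤ 2) and ≥ 70% alpha-shape area overlap
   with the postsynaptic marker, and restriction of analysis targets to the
   scaffold boundary (≥ 25 localizations each).
3. **Nanoclusters** — DBSCAN per analysis target (defaults ε = 25 nm,
   minPts = 5), size (≥ 5 localizations) and area-outlier (ROUT, Q = 0.1%)
   filters, alpha-shape geometry (alpha radius 0.9375 px = 150 nm), effective
   radius √(area/π), and the edge-corrected within-synapse pair
   autocorrelation g(r).
4. **Cross statistics** — density of protein B in radial bins around each
   protein-A nanocluster center, normalized to 100 uniform randomizations of B
   inside the scaffold polygon; per-nanocluster classification as
   enriched / indistinguishable / de-enriched by comparing the mean enrichment
   within 60 nm against the mean ± 1.96 SD of the statistic over 50
   independent randomizations; and the separation index

   SI = d / (r₁ + r₂),

   the centroid-to-centroid distance of a nanocluster and the nearest opposite
   nanocluster divided by the sum of the centroid-to-border distances along
   the connecting line (SI < 1 means the boundaries overlap).

## Worked example

```python
from aznano.pipeline import PipelineConfig, run_pipeline
from aznano.synthetic import simulate_field

tables, truth = simulate_field(seed=3, architecture="co_organized")
result = run_pipeline(tables, PipelineConfig(master_seed=1))
print(result.summary)
```

Running `examples/01_simulate_and_analyze.py` (the same computation with
commentary) prints:

```
planted nanoclusters: {'munc13': 4, 'cav2': 3}
synapses accepted: 1
detected nanoclusters: {'munc13': 4, 'cav2': 3}
enriched fraction per target: {'munc13': 0.75, 'cav2': 1.0}
SI<1 (overlapping) fraction: {'munc13': 0.75, 'cav2': 1.0}
```

The simulated field plants four Munc13-1 and three CaV2.1 nanoclusters with
shared centers inside one en-face synapse; the pipeline accepts the synapse,
recovers both planted counts, and — because the architectures coincide —
classifies the three paired Munc13-1 nanoclusters (and all CaV2.1
nanoclusters) as enriched with overlapping boundaries, while the unpaired
fourth Munc13-1 nanocluster is not. `examples/02_architecture_comparison.py`
contrasts this with segregated fields, where both fractions drop to zero.
Further examples cover drift/chromatic corrections and the STED line-profile
chain; a thin CLI (`aznano simulate`, `aznano run`) wraps the same functions
for shell use.

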