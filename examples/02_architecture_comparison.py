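"""Co-organized vs segregated nanocluster architectures.

Runs the pipeline on matched synthetic fields where the two analysis proteins
either share nanocluster centers or avoid each other, and compares the
enriched fraction and the separation-index overlap fraction. This is the
qualitative signature the analysis is designed to detect: co-organization
raises cross-enrichment and pushes SI below 1.
"""

import warnings

import numpy as np

from aznano.pipeline import PipelineConfig, run_pipeline
from aznano.synthetic import simulate_field

warnings.filterwarnings("ignore")

for arch in ("co_organized", "segregated", "independent"):
    enriched, overlap = [], []
    for seed in range(5):
        tables, _ = simulate_field(seed=seed, architecture=arch)
        res = run_pipeline(tables, PipelineConfig(master_seed=seed))
        if len(res.classification):
            enriched.extend((res.classification["label"] == "enriched").tolist())
        if len(res.separation):
            overlap.extend(res.separation["overlap"].tolist())
    print(f"{arch:>13}: enriched {100 * np.mean(enriched):5.1f}%   "
          f"SI<1 {100 * np.mean(overlap):5.1f}%   (n={len(enriched)} nanoclusters)")
# co_organized should rank highest on both, segregated lowest
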