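"""Generate the packaged regression fixture: a small four-target synthetic
field written as CSV plus a manifest of the filter/selection counts the
pipeline produces on it. The counts are frozen at fixture creation; the
regression test asserts the pipeline still reproduces them exactly.

Run from the repository root:  python scripts/make_fixture.py
"""

import json
from pathlib import Path

from aznano.locio import read_localizations, write_localizations
from aznano.pipeline import PipelineConfig, run_pipeline
from aznano.synthetic import FieldParams, simulate_field

OUT = Path(__file__).resolve().parent.parent / "tests" / "data"

FIXTURE_PARAMS = FieldParams(
    architecture="co_organized",
    synapse_radius_nm=150.0,
    scaffold_events=250,
    n_clusters_a=3,
    n_clusters_b=2,
    min_center_sep_nm=80.0,
    events_per_cluster_a=45,
    events_per_cluster_b=45,
    nonspecific_events=170,
    n_nonspecific=1,
    mean_on_frames=1.5,
    bad_fraction=0.05,
)
FIXTURE_SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables, gt = simulate_field(FIXTURE_PARAMS, seed=FIXTURE_SEED)
    for name, tab in tables.items():
        # write with reduced precision to keep the fixture small; counts below
        # are computed from the re-read files so rounding is part of the fixture
        tab.df["x_nm"] = tab.df["x_nm"].round(2)
        tab.df["y_nm"] = tab.df["y_nm"].round(2)
        tab.df["photons"] = tab.df["photons"].round(1)
        tab.df["sigma_px"] = tab.df["sigma_px"].round(3)
        tab.df["precision_nm"] = tab.df["precision_nm"].round(2)
        write_localizations(tab, OUT / f"{name}.csv")

    reread = {
        name: read_localizations(
            OUT / f"{name}.csv", "csv", pixel_size_nm=160.0, n_frames=30000, target_id=name
        )
        for name in tables
    }
    result = run_pipeline(reread, PipelineConfig(master_seed=0))
    manifest = {
        "seed": FIXTURE_SEED,
        "total_rows": int(sum(len(t) for t in reread.values())),
        "counts": result.manifest["counts"],
    }
    (OUT / "fixture_manifest.json").write_text(json.dumps(manifest, indent=1))
    print(json.dumps(manifest, indent=1))


if __name__ == "__main__":
    main()
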