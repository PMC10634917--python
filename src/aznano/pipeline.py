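"""End-to-end pipeline: preprocessing -> synapse selection -> nanocluster and
cross-enrichment analysis, with a reproducible configuration and manifest.

Stage order: quality filter -> drift correction (RCC) -> chromatic correction
(bead t-form, if control points are provided) -> residual offset to the
reference analysis target -> temporal linking -> scaffold DBSCAN and synapse
selection -> per-synapse nanocluster detection, autocorrelation,
randomization-normalized cross-enrichment, classification and separation
index. Randomization seeds derive from the master seed per (synapse, protein,
purpose), so adding synapses does not perturb other synapses' draws.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross_stats, nanoclusters, preprocess, synapse_select
from .errors import InsufficientDataError
from .locio import LocalizationTable

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_results"]


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters; every field is echoed into the run manifest."""

    # target roles
    synapse_mask: str = "bassoon"
    postsynaptic: str = "psd95"
    analysis_a: str = "munc13"
    analysis_b: str = "cav2"
    # preprocessing
    sigma_bounds_px: tuple[float, float] = (0.3, 1.6)
    precision_max_nm: float = 20.0
    photon_bin_width: float = 50.0
    link_radius_px: float = 0.3
    max_dark_frames: int = 5
    drift_correction: bool = False
    undrift_segment_frames: int = 1000
    rcc_pixel_nm: float = 30.0
    residual_offset: bool = False
    # synapse selection
    synapse_eps_nm: float = 48.0
    synapse_min_points: int = 10
    synapse_min_size: int = 75
    frame_sd_bounds: tuple[float, float] = (2500.0, 11000.0)
    frame_mean_k_sigma: float = 2.0
    synapse_alpha_radius_nm: float = 150.0
    overlap_min: float = 0.70
    shape_metric_max: float = 2.0
    min_locs_in_zone: int = 25
    pair_max_dist_nm: float = 600.0
    # nanoclusters
    nc_eps_nm: float = 25.0
    nc_min_points: int = 5
    nc_alpha_radius_nm: float = 150.0
    nc_min_locs: int = 5
    rout_q: float = 0.001
    # enrichment
    bin_edges_nm: tuple = tuple(np.arange(0.0, 210.0, 10.0))
    n_rand_norm: int = 100
    n_rand_class: int = 50
    enrichment_r_max_nm: float = 60.0
    enrichment_k_sd: float = 1.96
    autocorr_min_points: int = 25
    # seeding
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges_nm"] = list(map(float, d["bin_edges_nm"]))
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("sigma_bounds_px", "frame_sd_bounds", "bin_edges_nm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclasses.dataclass
class PipelineResult:
    qc_reports: dict
    drift_trajectory: np.ndarray | None
    rois: list
    nanoclusters: dict  # (roi_id, target) -> list[Nanocluster]
    classification: pd.DataFrame
    separation: pd.DataFrame
    enrichment_curves: dict  # direction -> (bin_edges, smoothed per-nc matrix)
    autocorrelation: dict  # (roi_id, target) -> AutocorrelationCurve
    summary: dict
    manifest: dict


def _cluster_points(table: LocalizationTable, labels: np.ndarray, lab: int) -> np.ndarray:
    return table.xy[labels == lab]


def _roi_seed(master: int, roi_id: int, protein: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master, roi_id, protein, purpose]))


def run_pipeline(
    tables: dict[str, LocalizationTable],
    config: PipelineConfig | None = None,
    bead_pairs: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> PipelineResult:
    """Run the full analysis on a dict of per-target localization tables."""
    cfg = config or PipelineConfig()
    manifest: dict = {"config": cfg.to_dict(), "counts": {}, "version": _version()}
    counts = manifest["counts"]

    # --- preprocessing -------------------------------------------------------
    qc_reports = {}
    work: dict[str, LocalizationTable] = {}
    for name, tab in tables.items():
        filtered, report = preprocess.filter_quality(
            tab, cfg.sigma_bounds_px, cfg.precision_max_nm, cfg.photon_bin_width
        )
        qc_reports[name] = report
        work[name] = filtered
        counts[f"{name}/rows_in"] = report.rows_in
        counts[f"{name}/rows_after_quality"] = report.rows_out

    drift = None
    if cfg.drift_correction:
        combined = pd.concat([t.df for t in work.values()], ignore_index=True)
        ref = next(iter(work.values()))
        combo = LocalizationTable(
            combined, pixel_size_nm=ref.pixel_size_nm, n_frames=ref.n_frames, target_id="combined"
        )
        _, drift = preprocess.drift_correct_rcc(combo, cfg.undrift_segment_frames, cfg.rcc_pixel_nm)
        for name, tab in work.items():
            df = tab.df.copy()
            fr = df["frame"].to_numpy(int)
            df["x_nm"] = df["x_nm"].to_numpy(float) - drift[fr, 0]
            df["y_nm"] = df["y_nm"].to_numpy(float) - drift[fr, 1]
            work[name] = tab.with_df(df)

    if bead_pairs:
        for name, (fixed, moving) in bead_pairs.items():
            if name in work:
                model = preprocess.fit_chromatic_transform(fixed, moving)
                work[name] = preprocess.apply_transform(model, work[name])

    if cfg.residual_offset:
        ref = work[cfg.analysis_a]
        for name in work:
            if name != cfg.analysis_a:
                work[name], _, _ = preprocess.correct_residual_offset(ref, work[name])

    for name, tab in work.items():
        work[name] = preprocess.link_localizations(tab, cfg.link_radius_px, cfg.max_dark_frames)
        counts[f"{name}/rows_after_link"] = len(work[name])

    # --- synapse selection ---------------------------------------------------
    def scaffold_clusters(name):
        tab = work[name]
        labels = synapse_select.detect_synaptic_clusters(
            tab, cfg.synapse_eps_nm, cfg.synapse_min_points, cfg.synapse_min_size
        )
        n_before = len([l for l in np.unique(labels) if l >= 0])
        labels = synapse_select.remove_nonspecific_clusters(
            tab, labels, cfg.frame_sd_bounds, cfg.frame_mean_k_sigma
        )
        n_after = len([l for l in np.unique(labels) if l >= 0])
        counts[f"{name}/clusters_detected"] = n_before
        counts[f"{name}/clusters_after_frame_filter"] = n_after
        return tab, labels

    mask_tab, mask_labels = scaffold_clusters(cfg.synapse_mask)
    psd_tab, psd_labels = scaffold_clusters(cfg.postsynaptic)
    psd_centroids = {
        int(l): psd_tab.xy[psd_labels == l].mean(axis=0)
        for l in np.unique(psd_labels)
        if l >= 0
    }

    rois = []
    roi_id = 0
    for lab in sorted(int(l) for l in np.unique(mask_labels) if l >= 0):
        bas_pts = _cluster_points(mask_tab, mask_labels, lab)
        bas_centroid = bas_pts.mean(axis=0)
        if not psd_centroids:
            continue
        dists = {l: np.linalg.norm(c - bas_centroid) for l, c in psd_centroids.items()}
        best = min(sorted(dists), key=lambda l: dists[l])
        if dists[best] > cfg.pair_max_dist_nm:
            continue
        psd_pts = _cluster_points(psd_tab, psd_labels, best)
        roi = synapse_select.select_enface(
            bas_pts, psd_pts, cfg.synapse_alpha_radius_nm, cfg.overlap_min, cfg.shape_metric_max
        )
        roi.synapse_id = roi_id
        if roi.accepted:
            roi = synapse_select.restrict_to_active_zone(
                roi,
                {
                    cfg.analysis_a: work[cfg.analysis_a],
                    cfg.analysis_b: work[cfg.analysis_b],
                    cfg.postsynaptic: work[cfg.postsynaptic],
                },
                cfg.min_locs_in_zone,
            )
        rois.append(roi)
        roi_id += 1
    accepted = [r for r in rois if r.accepted]
    counts["synapses_candidate"] = len(rois)
    counts["synapses_accepted"] = len(accepted)

    # --- nanoclusters (detect per synapse, area-filter across the dataset) ---
    nc_all: dict = {}
    for roi in accepted:
        for target in (cfg.analysis_a, cfg.analysis_b):
            pts = roi.restricted[target].xy
            ncs = nanoclusters.detect_nanoclusters(
                pts, cfg.nc_eps_nm, cfg.nc_min_points, cfg.nc_alpha_radius_nm, target=target
            )
            nc_all[(roi.synapse_id, target)] = ncs
    for target in (cfg.analysis_a, cfg.analysis_b):
        pool = [(key, nc) for key, ncs in nc_all.items() if key[1] == target for nc in ncs]
        kept = nanoclusters.filter_nanoclusters(
            [nc for _, nc in pool], cfg.nc_min_locs, cfg.rout_q
        )
        kept_ids = {id(nc) for nc in kept}
        for key in [k for k in nc_all if k[1] == target]:
            nc_all[key] = [nc for nc in nc_all[key] if id(nc) in kept_ids]
        counts[f"{target}/nanoclusters"] = sum(
            len(v) for k, v in nc_all.items() if k[1] == target
        )

    # --- autocorrelation, cross-enrichment, classification, separation -------
    autocorr = {}
    class_rows = []
    sep_rows = []
    enr_store: dict[str, list] = {f"{cfg.analysis_a}->{cfg.analysis_b}": [],
                                  f"{cfg.analysis_b}->{cfg.analysis_a}": []}
    edges = np.asarray(cfg.bin_edges_nm, float)
    proteins = {cfg.analysis_a: 0, cfg.analysis_b: 1}
    for roi in accepted:
        poly = roi.bassoon_polygon
        for target in proteins:
            try:
                autocorr[(roi.synapse_id, target)] = nanoclusters.autocorrelation(
                    roi.restricted[target].xy, poly, edges, cfg.autocorr_min_points
                )
            except InsufficientDataError:
                pass
        for src, opp in ((cfg.analysis_a, cfg.analysis_b), (cfg.analysis_b, cfg.analysis_a)):
            src_ncs = nc_all.get((roi.synapse_id, src), [])
            opp_ncs = nc_all.get((roi.synapse_id, opp), [])
            pts_opp = roi.restricted[opp].xy
            if not src_ncs or len(pts_opp) == 0:
                continue
            rng_norm = _roi_seed(cfg.master_seed, roi.synapse_id, proteins[opp], 0)
            rng_class = _roi_seed(cfg.master_seed, roi.synapse_id, proteins[opp], 1)
            norm_sets = cross_stats.randomize_in_roi(len(pts_opp), poly, cfg.n_rand_norm, rng_norm)
            class_sets = cross_stats.randomize_in_roi(len(pts_opp), poly, cfg.n_rand_class, rng_class)
            for nc in src_ncs:
                profile = cross_stats.cross_enrichment(
                    nc.centroid_nm[None, :], pts_opp, poly, edges, rand_sets_b=norm_sets
                )
                label, stat, mu, sd = cross_stats.classify_enrichment(
                    profile, class_sets, cfg.enrichment_r_max_nm, cfg.enrichment_k_sd
                )
                enr_store[f"{src}->{opp}"].append(profile.enrichment)
                class_rows.append(
                    dict(
                        synapse_id=roi.synapse_id, target=src, nc_id=nc.cluster_id,
                        statistic=stat, rand_mean=mu, rand_sd=sd, label=label,
                        n_locs=nc.n_locs, area_nm2=nc.area_nm2,
                        effective_radius_nm=nc.effective_radius_nm,
                    )
                )
                if opp_ncs:
                    sep = cross_stats.separation_index(nc, opp_ncs)
                    sep_rows.append(
                        dict(
                            synapse_id=roi.synapse_id, target=src, nc_id=nc.cluster_id,
                            opposite_id=sep.opposite_id, d_nm=sep.d_nm, r1_nm=sep.r1_nm,
                            r2_nm=sep.r2_nm, si=sep.si, overlap=sep.overlap,
                        )
                    )

    classification = pd.DataFrame(class_rows)
    separation = pd.DataFrame(sep_rows)
    curves = {}
    for direction, mat in enr_store.items():
        if mat:
            smoothed = cross_stats.smooth_profiles_across_synapses(np.vstack(mat), cfg.rout_q)
            curves[direction] = {"bin_edges_nm": edges, "curves": smoothed}

    summary = _summarize(cfg, classification, separation)
    manifest["counts"].update(
        {f"classified/{k}": v for k, v in summary.get("n_classified", {}).items()}
    )
    return PipelineResult(
        qc_reports=qc_reports,
        drift_trajectory=drift,
        rois=rois,
        nanoclusters=nc_all,
        classification=classification,
        separation=separation,
        enrichment_curves=curves,
        autocorrelation=autocorr,
        summary=summary,
        manifest=manifest,
    )


def _summarize(cfg: PipelineConfig, classification: pd.DataFrame, separation: pd.DataFrame) -> dict:
    summary: dict = {"enriched_fraction": {}, "si_overlap_fraction": {}, "n_classified": {}}
    for target in (cfg.analysis_a, cfg.analysis_b):
        if len(classification):
            sub = classification[
                (classification["target"] == target) & (classification["label"] != "unclassifiable")
            ]
            summary["n_classified"][target] = int(len(sub))
            if len(sub):
                summary["enriched_fraction"][target] = float((sub["label"] == "enriched").mean())
        if len(separation):
            sub = separation[separation["target"] == target]
            if len(sub):
                summary["si_overlap_fraction"][target] = float(sub["overlap"].mean())
                summary.setdefault("si_median", {})[target] = float(sub["si"].median())
    return summary


def _version() -> str:
    from . import __version__

    return __version__


def write_results(result: PipelineResult, outdir) -> None:
    """Write result tables (CSV), ROI polygons and the manifest (JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.classification.to_csv(out / "classification.csv", index=False)
    result.separation.to_csv(out / "separation_index.csv", index=False)
    rois = []
    for roi in result.rois:
        entry = {
            "synapse_id": roi.synapse_id,
            "accepted": roi.accepted,
            "reason": roi.reason,
            "overlap_fraction": roi.overlap_fraction,
            "shape_metric": roi.shape_metric,
        }
        if roi.bassoon_polygon is not None:
            from ._geometry import largest_polygon

            entry["bassoon_polygon_nm"] = np.asarray(
                largest_polygon(roi.bassoon_polygon).exterior.coords
            ).tolist()
        rois.append(entry)
    (out / "synapses.json").write_text(json.dumps(rois, indent=1))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1, default=str))
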