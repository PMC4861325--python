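"""End-to-end demo pipeline: phantom -> cube -> NMF/K-Means -> annotation -> oPLS-DA.

Every stage consumes named seeds derived from the config seed; all outputs
are delimited text plus a machine-readable ``summary.json``.  A stage
failure raises :class:`StageError` carrying the stage name and a distinct
exit code.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classification as clf
from . import clustering, datacube, factorization, io, phantom
from .config import PipelineConfig

log = logging.getLogger(__name__)

STAGE_EXIT_CODES = {
    "phantom": 10,
    "acquisition": 11,
    "cube": 12,
    "nmf": 13,
    "kmeans": 14,
    "ion_images": 15,
    "roi": 16,
    "annotation": 17,
    "serum": 18,
    "classification": 19,
    "report": 20,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, config: PipelineConfig):
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)
        self.config = config
        super().__init__(
            f"stage {stage!r} failed: {cause}\nresolved config: {json.dumps(config.to_dict())}"
        )


def _save_image(path: Path, image: np.ndarray) -> None:
    np.savetxt(path, image, delimiter=",", fmt="%.10g")


def run_demo(config: PipelineConfig, out_dir) -> Path:
    """Run the full workflow and write a report directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    log.info("resolved config: %s", config.to_dict())
    summary: dict = {"seed": config.seed}

    stage = "phantom"
    try:
        spec = phantom.default_phantom_spec(
            seed=config.seed,
            pixel_pitch_um=config.phantom.pixel_pitch_um,
            pixel_gain_sigma=config.phantom.pixel_gain_sigma,
            mz_jitter_sigma_at_ref=config.phantom.mz_jitter_sigma_at_ref,
            background_peak_rate=config.phantom.background_peak_rate,
        )
        labels, profiles = phantom.make_phantom(spec)
        _save_image(out / "phantom_labels.csv", labels)

        stage = "acquisition"
        acq = phantom.AcquisitionParams(
            velocity_x_um_s=config.acquisition.velocity_x_um_s,
            line_step_um=config.acquisition.line_step_um,
            scan_period_s=config.acquisition.scan_period_s,
        )
        stream, track = phantom.simulate_acquisition(labels, profiles, spec, acq)
        io.write_stage_track(track, out / "stage_track.tsv")
        summary["n_scans"] = len(stream)

        stage = "cube"
        axis = datacube.build_mz_axis(
            config.axis.mz_lo, config.axis.mz_hi, config.axis.ref_mz,
            config.axis.ref_bin_width, config.axis.ref_sigma,
        )
        cube = datacube.build_cube(stream, track, axis)
        summary["cube"] = {
            "shape": list(cube.shape),
            "nnz_fraction": cube.nnz_fraction,
            "dense_storage_bytes": cube.dense_storage_bytes,
        }
        tic = datacube.tic_image(cube)
        _save_image(out / "tic_image.csv", tic)

        stage = "nmf"
        V = cube.pixel_matrix()
        normV = float(np.sqrt((cube.values.data ** 2).sum()))
        nmf_errors = {}
        nmf_results = {}
        for k in config.nmf.ks:
            res = factorization.nmf_als(V, k=k, seed=config.seed + 100 + k,
                                        tol=config.nmf.tol, max_iter=config.nmf.max_iter)
            nmf_results[k] = res
            rel_err = float(np.sqrt(2.0 * res.final_objective) / normV)
            nmf_errors[k] = rel_err
            comps = factorization.normalize_component_set(res, cube.rows, cube.cols)
            kdir = out / f"nmf_k{k}"
            kdir.mkdir(exist_ok=True)
            for j, img in enumerate(comps.images):
                _save_image(kdir / f"component_{j}_image.csv", img)
            np.savetxt(kdir / "component_spectra.csv", comps.spectra,
                       delimiter=",", fmt="%.10g")
            np.savetxt(kdir / "objective_trace.csv", res.objective_trace, fmt="%.10g")
            log.info("NMF k=%d: %d iterations, relative error %.4g, nnz fraction %.3g",
                     k, res.iterations, rel_err, cube.nnz_fraction)
        summary["nmf_relative_error"] = {str(k): v for k, v in nmf_errors.items()}

        stage = "kmeans"
        km = clustering.kmeans_segment(V, k=config.kmeans.k, seed=config.seed + 200,
                                       n_init=config.kmeans.n_init,
                                       max_iter=config.kmeans.max_iter)
        _save_image(out / "kmeans_labels.csv", km.labels.reshape(cube.rows, cube.cols))
        np.savetxt(out / "kmeans_centroids.csv", km.centroids, delimiter=",", fmt="%.10g")
        summary["kmeans_inertia"] = km.inertia

        stage = "ion_images"
        ref = ann.load_reference_features()
        ion_dir = out / "ion_images"
        ion_dir.mkdir(exist_ok=True)
        for mz in ref["exp_mz"]:
            img = datacube.extracted_ion_image(cube, float(mz),
                                               config.annotation.ion_image_tol_mz)
            _save_image(ion_dir / f"mz_{mz:.4f}.csv", img)

        stage = "roi"
        pitch = config.phantom.pixel_pitch_um
        tumor_roi = datacube.ROISelection(center=(17.0, 44.0), semi_axes=(6.5, 6.0))
        roi_spectrum = datacube.roi_mean_spectrum(cube, tumor_roi)
        nz = np.flatnonzero(roi_spectrum)
        pd.DataFrame({"mz": cube.axis.centers[nz], "intensity": roi_spectrum[nz]}).to_csv(
            out / "tumor_roi_spectrum.csv", index=False)
        ratio, verdict = ann.chlorine_isotope_ratio(
            roi_spectrum, cube.axis.centers, 572.4815, tol=config.annotation.isotope_tol_mz)
        summary["tumor_roi_cl_ratio_572"] = {"ratio": ratio, "one_chlorine": bool(verdict)}
        peaks = ann.list_major_peaks(roi_spectrum, cube.axis.centers,
                                     config.annotation.major_peak_threshold_percent)
        pd.DataFrame(peaks, columns=["mz", "relative_percent"]).to_csv(
            out / "tumor_roi_major_peaks.csv", index=False)

        stage = "annotation"
        feats = ann.annotate_reference_table(ref)
        serum_mz = [f.exp_mz for f in feats if f.serum_overlap]
        feats = ann.cross_reference(feats, serum_mz, config.annotation.cross_reference_tol_mz)
        n_ions, n_metabolites, _ = ann.dedupe_metabolites(feats)
        table = pd.DataFrame(
            {
                "exp_mz": [f.exp_mz for f in feats],
                "neutral_formula": [str(f.neutral_formula) for f in feats],
                "adduct": [f.adduct.name for f in feats],
                "theo_mz": [f.theo_mz_rounded for f in feats],
                "ppm": [f.ppm for f in feats],
                "identity": [f.identity for f in feats],
                "serum_overlap": [f.serum_overlap for f in feats],
            }
        )
        table.to_csv(out / "annotation_table.csv", index=False)
        summary["annotation"] = {
            "n_ions": n_ions,
            "n_metabolites": n_metabolites,
            "n_serum_overlap": int(table["serum_overlap"].sum()),
        }

        stage = "serum"
        serum_spec = phantom.default_serum_spec(
            seed=config.seed + 300, n_case=config.serum.n_case,
            n_control=config.serum.n_control,
            effect_scale=config.serum.effect_scale, sigma=config.serum.sigma)
        X, y = phantom.simulate_serum(serum_spec)
        io.write_serum_table(X, y, [f.feature_id for f in serum_spec.features],
                             out / "serum_table.csv")

        stage = "classification"
        report = clf.loo_cross_validate(X, y, n_orth=config.classification.n_orth,
                                        autoscale=config.classification.autoscale)
        model = clf.opls_da_fit(X, y, n_orth=config.classification.n_orth,
                                autoscale=config.classification.autoscale)
        summary["classification"] = {
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "n_misclassified": report.n_misclassified,
            "confusion": report.confusion,
            "n_lv": model.n_lv,
            "var_x_percent": round(model.var_x_percent, 2),
            "var_y_percent": round(model.var_y_percent, 2),
        }

        stage = "report"
        with (out / "summary.json").open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc, config) from exc
    return out
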