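"""End-to-end orchestration: named fixtures, full experiment runs, and the
on-disk report.

An experiment builds the phantom, runs the requested scan mode(s), validates
the winning slice's saliency mask against ground truth (Dice/IoU), computes
coverage, and writes a deterministic JSON report plus CSV/PNG/NIfTI
artifacts.  Reports contain no timestamps: two runs with the same seed are
byte-identical.  Wall-clock timings go to the separate run log only.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._util import ValidationError, stable_seed
from .bmode import acquire, save_image
from .config import PhantomConfig, RunConfig, dump_config
from .geometry import GantryGeometry, ProbePose, enumerate_stations
from .phantom import LesionSpec, Phantom, build_phantom, two_tumor_layout
from .scoring import AnalyticScorer, ScorerSpec, dice_iou, occlusion_saliency, saliency_to_mask
from .search import (
    ScanConfig,
    ScanResult,
    compare_linear_angular,
    coverage_map,
    optimal_slice_search,
    zigzag_indices,
)

__all__ = ["make_fixture", "build_phantom_from_config", "schedule_poses", "run_experiment"]

logger = logging.getLogger("gantryscan")

FIXTURE_NAMES = ("single_centered", "two_tumor", "off_axis_only")


def make_fixture(name: str, seed: int = 0) -> tuple[RunConfig, Phantom]:
    """Named validation layouts used throughout the test suite.

    ``single_centered``
        One 14 mm sphere on the central scan line — the benign case where a
        coarse-to-fine search must agree exactly with exhaustive search.
    ``two_tumor``
        The classic two-lesion gantry-validation layout: tumor 1 (14 mm) on
        the central scan line, tumor 2 (18 mm) laterally offset 42 mm so no
        untilted plane reaches it, but the +/-14 degree roll sweep does.
    ``off_axis_only``
        Only the off-axis lesion: every zero-angle slice is lesion-free.
    """
    if name not in FIXTURE_NAMES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    extent = (160.0, 120.0, 60.0)
    if name == "single_centered":
        lesions = (LesionSpec.sphere((80.0, 60.0, 30.0), 14.0),)
        scan = ScanConfig(
            slin0=16.0, nstep=9, x_start=16.0, s_theta=2, alpha=2.0,
            epsilon=2.0, theta_max=10.0, phi_max=10.0,
        )
    else:
        both = two_tumor_layout(14.0, 18.0, 42.0, extent=extent)
        lesions = tuple(both) if name == "two_tumor" else (both[1],)
        scan = ScanConfig(
            slin0=10.0, nstep=13, x_start=10.0, s_theta=7, alpha=2.0,
            epsilon=2.0, theta_max=16.0, phi_max=16.0,
        )
    config = RunConfig(
        phantom=PhantomConfig(extent=extent, lesions=lesions),
        geometry=GantryGeometry(),
        scan=scan,
        scorer=ScorerSpec(),
        seed=int(seed),
    )
    config.validate()
    return config, build_phantom_from_config(config)


def build_phantom_from_config(config: RunConfig) -> Phantom:
    pc = config.phantom
    return build_phantom(
        extent=pc.extent,
        spacing=pc.spacing,
        background_echogenicity=pc.background_echogenicity,
        lesions=list(pc.lesions),
        texture_seed=stable_seed(config.seed, "texture"),
        texture_amplitude=pc.texture_amplitude,
        texture_smoothing=pc.texture_smoothing,
    )


def schedule_poses(scan: ScanConfig, geometry: GantryGeometry,
                   angular: bool) -> list[ProbePose]:
    """The full round-0 acquisition schedule (the sweep the gantry executes
    before any refinement): every station's untilted pose, plus, in angular
    mode, the whole pitch-roll lattice at each station.

    Coverage analysis runs on this schedule, so the angular pose set is by
    construction a superset of the linear one.
    """
    stations = enumerate_stations(scan.x_start, scan.slin0, scan.nstep, geometry)
    poses = [ProbePose(x=x) for x in stations]
    if angular:
        lattice = zigzag_indices(scan.s_theta, 1)
        for x in stations:
            poses.extend(
                ProbePose(x=x, pitch=scan.alpha * i, roll=scan.alpha * j)
                for (i, j) in lattice
            )
    return poses


def _scorer_from_spec(spec: ScorerSpec):
    if spec.kind != "analytic":
        raise ValidationError(
            "run_experiment needs an analytic scorer; black-box scorers are "
            "supplied programmatically"
        )
    return AnalyticScorer(spec.calibration_halfsat)


def _result_summary(result: ScanResult) -> dict:
    return {
        "mode": result.mode,
        "Lmax": {"x_mm": round(result.Lmax.x, 9),
                 "pitch_deg": result.Lmax.pitch,
                 "roll_deg": result.Lmax.roll},
        "Pmax": result.Pmax,
        "n_evaluations": result.n_evaluations,
        "rounds": [
            {"step_mm": r.step, "window_mm": list(r.window),
             "n_stations": len(r.stations), "best_score": r.best_score}
            for r in result.rounds
        ],
    }


def _evaluations_frame(result: ScanResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [e.pose.x for e in result.evaluations],
            "pitch": [e.pose.pitch for e in result.evaluations],
            "roll": [e.pose.roll for e in result.evaluations],
            "probability": [e.probability for e in result.evaluations],
            "round": [e.round_index for e in result.evaluations],
            "order": [e.order for e in result.evaluations],
        }
    )


def run_experiment(
    config: RunConfig,
    out_dir,
    mode: str = "compare",
    save_images: bool = True,
    coverage_stride: int = 2,
) -> dict:
    """Run the full pipeline and write the report.

    ``mode`` is ``"linear"``, ``"angular"`` or ``"compare"`` (both, with a
    per-lesion detection table).  Returns the report dict; on disk it lands
    as ``report.json`` next to the evaluation CSVs, the winning slice and
    its saliency/mask PNGs, and the coverage map (uncompressed NIfTI).
    """
    if mode not in ("linear", "angular", "compare"):
        raise ValidationError(f"unknown mode {mode!r}")
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    inventory: list[str] = ["report.json", "run.log"]
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                dt = time.perf_counter() - self.t0
                timings[name] = dt
                logger.info("stage %s finished in %.2f s", name, dt)

        return _T()

    try:
        with _stage("phantom"):
            phantom = build_phantom_from_config(config)
        scorer = _scorer_from_spec(config.scorer)
        scan = config.scan
        geometry = config.geometry

        report: dict = {
            "seed": config.seed,
            "mode": mode,
            "config_yaml": dump_config(config),
            "lesions": [
                {"label": k + 1, "center_mm": list(l.center),
                 "radii_mm": list(l.radii), "echogenicity": l.echogenicity}
                for k, l in enumerate(config.phantom.lesions)
            ],
        }

        results: dict[str, ScanResult] = {}
        with _stage("scan"):
            if mode == "compare":
                cmp = compare_linear_angular(scan, geometry, phantom, scorer,
                                             seed=config.seed)
                results = {"linear": cmp.linear, "angular": cmp.angular}
                report["detection_threshold"] = cmp.detection_threshold
                report["lesion_detection"] = [
                    {
                        "label": d.label,
                        "linear_probability": d.linear_probability,
                        "angular_probability": d.angular_probability,
                        "detected_linear": d.detected_linear,
                        "detected_angular": d.detected_angular,
                    }
                    for d in cmp.lesions
                ]
            else:
                results = {mode: optimal_slice_search(
                    scan, geometry, phantom, scorer,
                    seed=config.seed, angular=(mode == "angular"),
                )}
        report["results"] = {m: _result_summary(r) for m, r in results.items()}

        for m, result in results.items():
            csv_name = f"evaluations_{m}.csv"
            _evaluations_frame(result).to_csv(out / csv_name, index=False)
            inventory.append(csv_name)

        # saliency validation on the winning slice of the primary mode
        primary = "angular" if "angular" in results else mode
        best = results[primary]
        with _stage("saliency"):
            image = acquire(
                phantom, best.Lmax, geometry,
                pixel_spacing=scan.pixel_spacing,
                attenuation_coeff=scan.attenuation_coeff,
                noise_seed=stable_seed(config.seed, "speckle",
                                       (round(best.Lmax.x, 6),
                                        round(best.Lmax.pitch, 6),
                                        round(best.Lmax.roll, 6))),
                speckle=scan.speckle, gain=scan.gain,
            )
            saliency = occlusion_saliency(image, scorer, patch=8, stride=4)
            pred_mask = saliency_to_mask(saliency, 0.5)
            dice, iou = dice_iou(pred_mask, image.mask)
        report["saliency_validation"] = {
            "pose": _result_summary(best)["Lmax"],
            "dice": dice,
            "iou": iou,
            "predicted_area_px": int(pred_mask.sum()),
            "truth_area_px": int(image.mask.sum()),
        }
        if save_images:
            save_image(image, out / "best_slice.png", out / "best_slice_mask.png",
                       out / "best_slice.json")
            import imageio.v3 as iio

            iio.imwrite(out / "best_slice_saliency.png",
                        np.clip(np.rint(saliency * 255), 0, 255).astype(np.uint8))
            iio.imwrite(out / "best_slice_pred_mask.png",
                        pred_mask.astype(np.uint8) * 255)
            inventory += ["best_slice.png", "best_slice_mask.png", "best_slice.json",
                          "best_slice_saliency.png", "best_slice_pred_mask.png"]

        with _stage("coverage"):
            coverage = {}
            hits = {}
            for m in results:
                poses = schedule_poses(scan, geometry, angular=(m == "angular"))
                hit, tumor_frac, total_frac = coverage_map(
                    poses, geometry, phantom, voxel_stride=coverage_stride)
                coverage[m] = {"tumor_fraction": tumor_frac,
                               "total_fraction": total_frac}
                hits[m] = hit
        report["coverage"] = coverage
        for m, hit in hits.items():
            aff = np.eye(4)
            aff[:3, :3] = np.diag(np.asarray(config.phantom.spacing) * coverage_stride)
            name = f"coverage_{m}.nii"
            nib.save(nib.Nifti1Image(hit.astype(np.uint8), aff), str(out / name))
            inventory.append(name)

        report["inventory"] = sorted(inventory)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
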