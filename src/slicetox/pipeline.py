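"""End-to-end orchestration: prep -> detect -> ratio filter -> coloc -> depth profiles.

The run report is a plain dict (serialized as JSON by the CLI) with the
stage-by-stage counts and fitted decay constants; identical config + seed
gives an identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import bleedthrough, coloc, depthprofile, detect, prep, synthetic
from .config import RunConfig
from .errors import SlicetoxError

log = logging.getLogger(__name__)


class StageFailure(SlicetoxError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _load_inputs(cfg: RunConfig):
    if cfg.preset is not None:
        scfg = synthetic.stack_preset(cfg.preset, seed=cfg.seed, **cfg.synthetic)
        green, red, truth = synthetic.generate_stack(scfg)
        return green, red, truth
    green = prep.read_stack(cfg.green_path, prep.GREEN, cfg.pixel_size, cfg.z_step)
    red = prep.read_stack(cfg.red_path, prep.RED, cfg.pixel_size, cfg.z_step)
    if cfg.channels == ["red", "green"]:
        green, red = red, green
    return green, red, None


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Execute the full still-stack pipeline and write CSV/YAML/JSON artifacts.

    Returns the run report dict.  A failing stage raises StageFailure naming
    the stage.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"preset": cfg.preset, "seed": cfg.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except SlicetoxError:
                raise
            except Exception as e:  # noqa: BLE001 - report which stage died
                raise StageFailure(name, e) from e

        return deco

    green, red, truth = stage("input")(lambda: _load_inputs(cfg))
    if truth is not None:
        synthetic.write_truth(truth, out / "truth.csv")
    report["stages"]["input"] = {"n_planes": int(green.n_planes)}

    def _prep():
        return prep.preprocess_pair(
            green,
            red,
            group_size=cfg.group_size,
            smooth_radius=cfg.smooth_radius,
            eight_bit=cfg.eight_bit,
            joint_scale=cfg.joint_scale,
        )

    (gmips, gstats), (rmips, rstats) = stage("prep")(_prep)
    report["stages"]["prep"] = {"n_mips": len(gmips)}

    def _detect():
        specs = {
            prep.GREEN: detect.FilterSpec(*cfg.green_filter),
            prep.RED: detect.FilterSpec(*cfg.red_filter),
        }
        return detect.detect_stack(
            gmips,
            rmips,
            [s.sd for s in gstats],
            [s.sd for s in rstats],
            specs=specs,
            k=cfg.threshold_k,
            dedup_radius=cfg.dedup_radius,
        )

    dets = stage("detect")(_detect)
    green_dets, red_dets = dets[prep.GREEN], dets[prep.RED]
    green_dets.to_csv(out / "detections_green.csv")
    red_dets.to_csv(out / "detections_red.csv")
    report["stages"]["detect"] = {"n_green": len(green_dets), "n_red_raw": len(red_dets)}

    def _ratio():
        if cfg.ratio_refit:
            ratios = bleedthrough.ratios_of(red_dets, cfg.ratio_convention)
            model = bleedthrough.fit_ratio_gaussian(ratios)
            thr = model
            report["stages"]["ratio_model"] = {
                "mean": model.mean,
                "sd": model.sd,
                "threshold": model.threshold,
                "n_fit": model.n_fit,
            }
            model.to_yaml(out / "ratio_model.yaml")
        else:
            thr = cfg.ratio_threshold
        return bleedthrough.apply_ratio_filter(red_dets, thr, cfg.ratio_convention)

    kept, eliminated = stage("bleedthrough")(_ratio)
    eliminated.to_csv(out / "detections_red_eliminated.csv")
    kept.to_csv(out / "detections_red_kept.csv")
    report["stages"]["bleedthrough"] = {"n_kept": len(kept), "n_eliminated": len(eliminated)}

    pairs = stage("coloc")(
        lambda: coloc.match_centroids(kept, green_dets, cfg.match_radius, cfg.max_mip_gap)
    )
    coloc.write_pairs(pairs, out / "coloc_pairs.csv")
    report["stages"]["coloc"] = {"n_pairs": len(pairs)}

    def _profiles():
        edges = np.asarray(cfg.edges, dtype=float)
        result = {}
        for name, ds in (("red", kept), ("green", green_dets)):
            profile = depthprofile.normalize_profile(depthprofile.bin_by_depth(ds, edges))
            entry = {"counts": profile.counts.tolist()}
            nonzero = int((profile.counts > 0).sum())
            if nonzero >= 4:
                fit = depthprofile.fit_exponential(profile)
                entry.update(tau=fit.tau, r2=fit.r2, converged=fit.converged)
                if profile.total > 0:
                    entry["frac_0_90"] = depthprofile.fraction_within(profile, 90.0)
                    entry["depth_75pct"] = depthprofile.depth_for_fraction(profile, 0.75)
            result[name] = entry
        return result

    report["stages"]["depthprofile"] = stage("depthprofile")(_profiles)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
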