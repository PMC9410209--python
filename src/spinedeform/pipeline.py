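"""End-to-end orchestration: simulate -> register -> jacobian -> analyze -> stats.

A pipeline run takes either a phantom specification (self-contained
validation mode) or paths to real paired volumes with disc masks and
landmark/metadata tables, and produces a reproducible report bundle:
per-disc deformation records, deformation-map NIfTI volumes, heatmap
projections, registration QC (Dice/Jaccard of propagated masks), a
statistics table and a JSON manifest from which the run can be
reproduced.  With a fixed configuration and seed the CSV/JSON outputs
are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deformation import jacobian_map, render_heatmap
from .disc_analysis import (
    analyze_discs,
    dice_jaccard,
    propagate_mask,
    region_diff_vs_angle_change,
    disc_angle,
    _landmark_segment,
)
from .grid import ImageVolume
from .phantom import PhantomSpec, generate_phantom, write_phantom
from .registration import (
    RegistrationParams,
    register_bspline,
    register_rigid,
    resample_isotropic,
    transform_to_field,
    resample_with_transform,
)
from .stats import backward_eliminate, chan_label, kruskal_wallis, ols, pearson

logger = logging.getLogger("spinedeform")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``phantom`` is set (synthetic mode: volumes, masks, landmarks
    and metadata are generated) or ``inputs`` maps the keys ``unloaded``,
    ``loaded``, ``masks_unloaded``, ``masks_loaded``, ``landmarks_loaded``
    (optionally ``landmarks_unloaded``, ``metadata``) to files on disk.
    """

    phantom: PhantomSpec | None = None
    inputs: dict | None = None
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    n_regions: int = 5
    n_slices_regions: int = 3
    n_slices_profile: int = 9
    alpha: float = 0.05
    seed: int = 42

    def __post_init__(self):
        if self.phantom is None and self.inputs is None:
            self.phantom = PhantomSpec(seed=self.seed)
        if self.phantom is not None:
            self.phantom = dataclasses.replace(self.phantom, seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "phantom": dataclasses.asdict(self.phantom) if self.phantom else None,
            "inputs": self.inputs,
            "registration": dataclasses.asdict(self.registration),
            "n_regions": self.n_regions,
            "n_slices_regions": self.n_slices_regions,
            "n_slices_profile": self.n_slices_profile,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        phantom = d.get("phantom")
        reg = d.get("registration") or {}
        known = {f.name for f in dataclasses.fields(RegistrationParams)}
        reg = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in reg.items()
            if k in known
        }
        return cls(
            phantom=PhantomSpec.from_dict(phantom) if phantom else None,
            inputs=d.get("inputs"),
            registration=RegistrationParams(**reg),
            n_regions=d.get("n_regions", 5),
            n_slices_regions=d.get("n_slices_regions", 3),
            n_slices_profile=d.get("n_slices_profile", 9),
            alpha=d.get("alpha", 0.05),
            seed=d.get("seed", 42),
        )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _round_df(df: pd.DataFrame, ndigits: int = 10) -> pd.DataFrame:
    return df.round(ndigits)


def compute_stats(
    records: pd.DataFrame, alpha: float = 0.05, n_regions: int = 5
) -> pd.DataFrame:
    """Fig-5-style statistics table from the per-disc record table.

    Univariable fits of each deformation measure on each available disc
    characteristic; a multivariable fit and its backward-eliminated
    reduction when the sample size allows; plus a Kruskal-Wallis test of
    deformation across subregions.  Returns a tidy table with one row per
    (response, model, predictor).
    """
    rows: list[dict] = []
    characteristics = [
        c
        for c in ("pfirrmann", "height_mm", "tilt_angle_deg", "disc_angle_deg")
        if c in records.columns and records[c].notna().all()
    ]
    responses = ["mean_D"] + [
        c for c in records.columns if c.startswith("region") and c.endswith("_D")
    ]

    for resp in responses:
        y = records[resp]
        for char in characteristics:
            x = records[char].astype(float)
            try:
                r = pearson(x, y)
                uni = ols(y, records[[char]])
                rows.append(
                    {
                        "response": resp, "model": "univariable",
                        "predictor": char,
                        "beta": uni.params[char], "p": uni.pvalues[char],
                        "r2": uni.r_squared, "R": r.r,
                        "strength": chan_label(r.r),
                    }
                )
            except ValueError as e:
                logger.warning("univariable %s ~ %s skipped: %s", resp, char, e)
        n, p = len(records), len(characteristics)
        if p >= 2 and n > p + 1:
            try:
                multi = ols(y, records[characteristics].astype(float))
                for char in characteristics:
                    rows.append(
                        {
                            "response": resp, "model": "multivariable",
                            "predictor": char,
                            "beta": multi.params[char],
                            "p": multi.pvalues[char],
                            "r2": multi.r_squared, "R": np.nan, "strength": "",
                        }
                    )
                red = backward_eliminate(
                    y, records[characteristics].astype(float), alpha=alpha
                )
                for char in red.predictors:
                    rows.append(
                        {
                            "response": resp, "model": "backward",
                            "predictor": char,
                            "beta": red.params[char], "p": red.pvalues[char],
                            "r2": red.r_squared, "R": np.nan, "strength": "",
                        }
                    )
            except ValueError as e:
                logger.warning("multivariable %s skipped: %s", resp, e)

    region_cols = [f"region{r}_D" for r in range(1, n_regions + 1)]
    if all(c in records.columns for c in region_cols):
        groups = [records[c].dropna().to_numpy() for c in region_cols]
        if all(len(g) for g in groups):
            kw = kruskal_wallis(groups)
            rows.append(
                {
                    "response": "region_D", "model": "kruskal_wallis",
                    "predictor": "subregion", "beta": kw.h, "p": kw.p,
                    "r2": np.nan, "R": np.nan, "strength": "",
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(inputs: dict):
    unloaded = ImageVolume.from_nifti(inputs["unloaded"])
    loaded = ImageVolume.from_nifti(inputs["loaded"])
    masks_unl = ImageVolume.from_nifti(inputs["masks_unloaded"])
    masks_load = ImageVolume.from_nifti(inputs["masks_loaded"])
    lm_loaded = pd.read_csv(inputs["landmarks_loaded"])
    lm_unloaded = (
        pd.read_csv(inputs["landmarks_unloaded"])
        if inputs.get("landmarks_unloaded")
        else None
    )
    metadata = pd.read_csv(inputs["metadata"]) if inputs.get("metadata") else None
    return unloaded, loaded, masks_unl, masks_load, lm_loaded, lm_unloaded, metadata


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Returns the manifest dictionary.  On stage failure the partial
    outputs are moved under ``outdir/failed/`` and a :class:`StageError`
    is raised naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "files": [],
        "diagnostics": {},
    }
    files: list[str] = manifest["files"]
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    prev_level = logger.level
    if logger.getEffectiveLevel() > logging.INFO:
        logger.setLevel(logging.INFO)  # the run log always records INFO
    stage = "setup"
    try:
        # -- stage 1: simulate or load ------------------------------------
        stage = "simulate"
        truth = None
        if config.phantom is not None:
            unloaded, loaded, truth, metadata = generate_phantom(config.phantom)
            phantom_files = write_phantom(
                unloaded, loaded, truth, metadata, outdir / "phantom"
            )
            files.extend(f"phantom/{k}" for k in phantom_files)
            masks_unl = truth.masks_unloaded
            masks_load = truth.masks_loaded
            lm_loaded = truth.landmarks_loaded
            lm_unloaded = truth.landmarks_unloaded
            logger.info("phantom generated: %d discs", config.phantom.n_discs)
        else:
            (
                unloaded, loaded, masks_unl, masks_load,
                lm_loaded, lm_unloaded, metadata,
            ) = _load_inputs(config.inputs)

        # -- stage 2: registration ----------------------------------------
        stage = "register"
        reg = config.registration
        fixed, moving = unloaded, loaded
        if reg.resample_to_isotropic:
            fixed = resample_isotropic(fixed, reg.target_spacing)
            moving = resample_isotropic(moving, reg.target_spacing)
        rigid = register_rigid(fixed, moving, reg)
        logger.info(
            "rigid: angles %s rad, translation %s mm, converged=%s",
            rigid.angles, rigid.translation, rigid.converged,
        )
        transform = register_bspline(fixed, moving, rigid, reg)
        manifest["diagnostics"]["registration"] = {
            "rigid_converged": bool(rigid.converged),
            "min_forward_det": transform.info["min_forward_det"],
            "bending_weight": transform.info["bending_weight"],
            "monotone_descent": all(
                h["monotone"] for h in transform.info["history"]
            ),
        }
        logger.info(
            "bspline: min forward det %.4f (folding check %s)",
            transform.info["min_forward_det"],
            "OK" if transform.info["min_forward_det"] > 0 else "FAILED",
        )
        rigid.save(outdir / "transform_rigid.json")
        transform.save(outdir / "transform_bspline")
        files += [
            "transform_rigid.json", "transform_bspline.json",
            "transform_bspline_coeffs.nii.gz",
        ]

        # -- stage 3: deformation mapping ---------------------------------
        stage = "jacobian"
        u = transform_to_field(transform, unloaded)
        jmap = jacobian_map(u, unloaded.spacing)
        ImageVolume(jmap.d, unloaded.spacing, unloaded.origin).save(
            outdir / "deformation_D.nii.gz"
        )
        ImageVolume(jmap.det, unloaded.spacing, unloaded.origin).save(
            outdir / "jacobian_det.nii.gz"
        )
        warped = resample_with_transform(loaded, transform, unloaded)
        warped.save(outdir / "loaded_warped.nii.gz")
        files += [
            "deformation_D.nii.gz", "jacobian_det.nii.gz", "loaded_warped.nii.gz",
        ]
        for proj, name in (("sagittal", "heatmap_sagittal.png"),
                           ("head-feet", "heatmap_headfeet.png")):
            render_heatmap(jmap, masks_unl.data, outdir / name, projection=proj)
            files.append(name)

        # -- stage 4: disc analysis + QC ----------------------------------
        stage = "analyze"
        records = analyze_discs(
            jmap, masks_unl, landmarks=lm_loaded, metadata=metadata,
            n_regions=config.n_regions,
            n_slices_regions=config.n_slices_regions,
            n_slices_profile=config.n_slices_profile,
        )
        if lm_unloaded is not None:
            angles_unl = []
            for lab in records["disc_id"]:
                lower = _landmark_segment(lm_unloaded, int(lab), "superior_endplate_lower")
                upper = _landmark_segment(lm_unloaded, int(lab), "inferior_endplate_upper")
                angles_unl.append(disc_angle(lower, upper))
            records["disc_angle_deg_unloaded"] = angles_unl
            records["disc_angle_change"] = (
                records["disc_angle_deg"] - records["disc_angle_deg_unloaded"]
            )
        propagated = propagate_mask(masks_load, transform, unloaded)
        propagated.save(outdir / "masks_propagated.nii.gz")
        files.append("masks_propagated.nii.gz")
        overlap = dice_jaccard(propagated.data, masks_unl.data)
        qc = overlap.per_label.copy()
        qc.loc[len(qc)] = {
            "label": -1, "dice": overlap.mean_dice, "jaccard": overlap.mean_jaccard,
        }
        _round_df(qc).to_csv(outdir / "qc_overlap.csv", index=False)
        files.append("qc_overlap.csv")
        manifest["diagnostics"]["qc"] = {
            "mean_dice": overlap.mean_dice,
            "mean_jaccard": overlap.mean_jaccard,
        }
        _round_df(records).to_csv(outdir / "discs.csv", index=False)
        files.append("discs.csv")

        # -- stage 5: statistics ------------------------------------------
        stage = "stats"
        stats_df = compute_stats(records, alpha=config.alpha,
                                 n_regions=config.n_regions)
        _round_df(stats_df).to_csv(outdir / "stats.csv", index=False)
        files.append("stats.csv")
        if "disc_angle_change" in records.columns and len(records) >= 3:
            try:
                pairs, res = region_diff_vs_angle_change(records)
                manifest["diagnostics"]["region_diff_vs_angle_change"] = {
                    "R": res.r, "p": res.p, "n": res.n,
                }
            except ValueError as e:
                logger.warning("angle-change sub-analysis skipped: %s", e)

        files.append("run.log")
        manifest_path = outdir / "manifest.json"
        files.append("manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as e:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for item in list(outdir.iterdir()):
            if item.name != "failed":
                shutil.move(str(item), str(failed / item.name))
        if isinstance(e, StageError):
            raise
        raise StageError(stage, e) from e
    finally:
        logger.setLevel(prev_level)
        logger.removeHandler(handler)
        handler.close()
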