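"""File formats, run configuration and the end-to-end pipeline.

Masks come in as NIfTI volumes (nonzero = solid tumor pixel) or
filename-sorted directories of PNG/TIFF slices; clinical data as CSV;
configuration as YAML.  ``run_pipeline`` chains feature extraction,
clinical encoding, dominance grouping, classification and survival
association, writing one CSV per stage plus a run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as _clinical
from . import features as _features
from . import grouping as _grouping
from . import prediction as _prediction
from . import survival as _survival
from .volume import TumorVolume

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_mask_volume",
    "write_mask_volume",
    "binarize_ct",
    "run_pipeline",
]

_SLICE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class RunConfig:
    """Configuration for an end-to-end run."""

    masks_dir: str = None
    clinical_csv: str = None
    out_dir: str = "results"
    spacing: float | None = None
    hu_threshold: float = -500.0
    threshold: float = 0.6
    rlc_as_complement: bool = False
    hbm_ibm_list: tuple = _prediction.DEFAULT_HBM_IBMS
    folds: int = 10
    seed: int = 0
    losa_method: str = "directed"
    stage_encoding: dict | None = None
    classifier_families: tuple = _prediction.CLASSIFIER_FAMILIES

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def binarize_ct(ct: np.ndarray, roi: np.ndarray, hu_threshold: float = -500.0) -> np.ndarray:
    """Binarize a grayscale CT inside an ROI: solid where HU exceeds the threshold.

    The default -500 HU sits at the air/tissue boundary, so cavities and other
    gas-filled lucencies fall below it.
    """
    ct = np.asarray(ct, dtype=float)
    roi = np.asarray(roi).astype(bool)
    if ct.shape != roi.shape:
        raise ValueError("CT and ROI shapes differ")
    return (ct > hu_threshold) & roi


def _read_nifti(path: Path, spacing):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D volume, got {data.ndim}D")
    if spacing is None:
        zooms = img.header.get_zooms()[:2]
        spacing = tuple(float(z) for z in zooms) if all(z > 0 for z in zooms) else 1.0
    slices = [data[:, :, k] != 0 for k in range(data.shape[2])]
    return slices, spacing


def _read_slice_stack(path: Path, spacing):
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES)
    if not files:
        raise ValueError(f"{path}: no PNG/TIFF slices found")
    slices = []
    for f in files:
        arr = np.asarray(iio.imread(f))
        if arr.ndim == 3:  # collapse any color channels
            arr = arr.max(axis=-1)
        slices.append(arr != 0)
    return slices, (1.0 if spacing is None else spacing)


def read_mask_volume(path, spacing: float | None = None) -> TumorVolume:
    """Read a binary tumor volume from NIfTI or a directory of image slices.

    Nonzero pixels are solid tumor; slice order follows the NIfTI third axis
    or the filename sort.  Spacing comes from the NIfTI header when present,
    else the ``spacing`` argument, else 1.0 pixel units.
    """
    path = Path(path)
    try:
        if path.is_dir():
            slices, spacing = _read_slice_stack(path, spacing)
        else:
            slices, spacing = _read_nifti(path, spacing)
    except (OSError, ValueError) as err:
        raise ValueError(f"unreadable mask input {path}: {err}") from err
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"{path}: mixed slice dimensions {sorted(shapes)}")
    vol = TumorVolume.from_arrays(slices, spacing=spacing if spacing is not None else 1.0)
    if vol.n_tumor == 0:
        raise ValueError(f"{path}: no tumor pixels")
    return vol


def write_mask_volume(volume: TumorVolume, path) -> None:
    """Write the solid images of a volume as a NIfTI file (uint8, A stacked on axis 2)."""
    import nibabel as nib

    data = np.stack([sl.a.astype(np.uint8) for sl in volume.slices], axis=2)
    spacing = volume.slices[0].spacing if volume.slices else 1.0
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _load_volumes(masks_dir: Path, spacing) -> dict:
    volumes = {}
    entries = sorted(masks_dir.iterdir())
    for entry in entries:
        if entry.is_dir():
            volumes[entry.name] = read_mask_volume(entry, spacing)
        elif entry.name.endswith((".nii", ".nii.gz")):
            sid = entry.name.removesuffix(".nii.gz").removesuffix(".nii")
            volumes[sid] = read_mask_volume(entry, spacing)
    if not volumes:
        raise ValueError(f"no mask volumes found under {masks_dir}")
    return volumes


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> encode -> group -> predict -> survive and write CSVs.

    Subjects present in only one input stream are excluded with a logged
    reason; nothing is dropped silently.  Returns the in-memory results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exclusions: list = []

    volumes = _load_volumes(Path(config.masks_dir), config.spacing)
    ibm_df = _features.ibm_table(volumes, losa_method=config.losa_method)
    ibm_df.to_csv(out / "ibm_features.csv", index=False)

    raw = pd.read_csv(config.clinical_csv)
    encoded, excluded = _clinical.build_feature_table(raw, config.stage_encoding)
    exclusions += [(sid, reason) for sid, reason in excluded]
    encoded.to_csv(out / "cbm_encoded.csv", index=False)

    imaging_ids = set(ibm_df["subject_id"])
    clinical_ids = set(encoded["subject_id"])
    for sid in sorted(imaging_ids - clinical_ids):
        exclusions.append((sid, "no clinical record"))
    for sid in sorted(clinical_ids - imaging_ids):
        exclusions.append((sid, "no mask volume"))
    common = sorted(imaging_ids & clinical_ids)
    if not common:
        raise ValueError("no subjects present in both imaging and clinical inputs")
    ibm_df = ibm_df[ibm_df["subject_id"].isin(common)].reset_index(drop=True)
    encoded = encoded[encoded["subject_id"].isin(common)].reset_index(drop=True)

    groups = _grouping.group_table(
        ibm_df, threshold=config.threshold, rlc_as_complement=config.rlc_as_complement
    )
    groups.to_csv(out / "groups.csv", index=False)

    results = {"ibm": ibm_df, "cbm": encoded, "groups": groups, "exclusions": exclusions}

    survival_cols = {"time", "event"}
    if survival_cols <= set(raw.columns):
        cohort = encoded.merge(ibm_df, on="subject_id").merge(
            raw[["subject_id", "time", "event"]], on="subject_id"
        )
        cohort["five_year_label"] = _clinical.five_year_label(
            cohort["time"], cohort["event"]
        )
        classifiable = cohort.dropna(subset=["five_year_label"]).reset_index(drop=True)
        for sid in cohort.loc[cohort["five_year_label"].isna(), "subject_id"]:
            exclusions.append((sid, "censored before 5 years (classification only)"))
        sets = {
            "CBM": list(_clinical.CBM_COLUMNS),
            "IBM": list(_features.IBM_NAMES),
            "HBM": list(_clinical.CBM_COLUMNS) + list(config.hbm_ibm_list),
        }
        comparison = _prediction.compare_feature_sets(
            classifiable, sets, families=config.classifier_families,
            k=config.folds, seed=config.seed,
        )
        comparison.metrics.to_csv(out / "prediction_metrics.csv", index=False)
        comparison.idi.to_csv(out / "prediction_idi.csv", index=False)
        roc_rows = []
        for (family, name), pts in comparison.roc.items():
            pts = pts.assign(family=family, set=name)
            roc_rows.append(pts)
        pd.concat(roc_rows, ignore_index=True).to_csv(out / "roc_points.csv", index=False)
        results["comparison"] = comparison

        surv_rows, km_rows = [], []
        merged = groups.merge(cohort[["subject_id", "time", "event"]], on="subject_id")
        for ibm_name, sub in merged.groupby("ibm"):
            if sub["group"].nunique() < 2 or sub["event"].sum() == 0:
                logger.info("skipping survival association for %s: one group or no events", ibm_name)
                continue
            chi2, p = _survival.logrank(sub["time"], sub["event"], sub["group"])
            nsd = (sub["group"] == "NSD").astype(float)
            frame = pd.DataFrame({"time": sub["time"], "event": sub["event"], "nsd": nsd})
            try:
                cox = _survival.cox_fit(frame, ["nsd"])
                hr, ci_lo, ci_hi, cox_p = cox.summary.iloc[0][["hr", "ci_low", "ci_high", "p"]]
            except ValueError as err:
                logger.warning("Cox fit failed for %s: %s", ibm_name, err)
                hr = ci_lo = ci_hi = cox_p = np.nan
            row = {"ibm": ibm_name, "logrank_chi2": chi2, "logrank_p": p,
                   "hr_nsd": hr, "hr_ci_low": ci_lo, "hr_ci_high": ci_hi, "hr_p": cox_p}
            for label, grp in sub.groupby("group"):
                try:
                    summ = _survival.km_summary(grp["time"], grp["event"])
                except ValueError:
                    continue
                row[f"mean_{label}"] = summ["mean"]
                row[f"median_{label}"] = summ["median"]
                kmf = _survival.km_estimate(grp["time"], grp["event"])
                sf = kmf.survival_function_
                km_rows.append(pd.DataFrame({
                    "ibm": ibm_name, "group": label,
                    "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy(),
                }))
            surv_rows.append(row)
        if surv_rows:
            pd.DataFrame(surv_rows).to_csv(out / "survival_association.csv", index=False)
            pd.concat(km_rows, ignore_index=True).to_csv(out / "km_curves.csv", index=False)
            results["survival"] = pd.DataFrame(surv_rows)

    exclusion_df = pd.DataFrame(exclusions, columns=["subject_id", "reason"])
    exclusion_df.to_csv(out / "exclusions.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "config_digest": config.digest(),
                   "n_subjects": len(common), "n_excluded": len(exclusions)}, fh, indent=2)
    return results
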