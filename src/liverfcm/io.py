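"""Study I/O and report writing.

A study on disk is a NIfTI multi-echo stack (rows x cols x echoes, echo on
the third axis), a YAML sidecar listing the echo times in milliseconds, a
liver ROI label image and, optionally, a manual reference segmentation.
Label maps use the encoding 0 outside / 1 parenchyma / 2 vessel.

Reports are deterministic: JSON values are rounded to 4 decimals with
sorted keys and no timestamps, so re-running the same inputs reproduces
byte-identical files; full-precision arrays go to an ``.npz`` sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

from .errors import InputError
from .fcm import SegmentationMask
from .phantom import PhantomStudy
from .relaxometry import LICCalibration, MultiEchoStack, ScalarMap
from .schemes import OPResult, SAResult, SchemeOutcome

__all__ = [
    "read_study",
    "write_study",
    "read_mask",
    "write_mask",
    "write_map",
    "read_map",
    "read_calibration",
    "write_report",
]

_AFFINE = np.eye(4)

LABEL_ENCODING = {"outside": 0, "parenchyma": 1, "vessel": 2}


def _round(obj):
    """Recursively round floats to 4 decimals for byte-stable JSON."""
    if isinstance(obj, float):
        return round(obj, 4)
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 4)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_round(payload), indent=2, sort_keys=True) + "\n")


def write_study(study: PhantomStudy, out_dir: str | Path) -> dict:
    """Write a phantom study as a loadable on-disk study (stack + TE sidecar
    + ROI + ground-truth labels + true maps + config echo)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack_data = np.moveaxis(study.stack.echoes, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack_data, _AFFINE), out / "stack.nii")
    (out / "tes.yaml").write_text(yaml.safe_dump(
        {"te_ms": [float(t) for t in study.stack.te_ms]}))
    write_mask(SegmentationMask.from_vessel_mask(
        np.zeros_like(study.roi), study.roi, source="roi"), out / "roi.nii")
    write_mask(study.truth, out / "truth.nii")
    write_map(study.true_r2star, out / "true_r2star.nii")
    write_map(study.true_lic, out / "true_lic.nii")
    cfg = dataclasses.asdict(study.config)
    cfg["te_ms"] = [float(t) for t in study.config.te_ms]
    meta = {"config": cfg, "lic_level": study.lic_level,
            "label_encoding": LABEL_ENCODING}
    _write_json(out / "truth.json", meta)
    return meta


def read_study(stack_path: str | Path, te_path: str | Path, roi_path: str | Path,
               reference_path: str | Path | None = None
               ) -> tuple[MultiEchoStack, np.ndarray, SegmentationMask | None]:
    """Load and validate a study: stack + TE sidecar + ROI (+ optional
    manual reference).  Raises :class:`InputError` naming the offending
    shapes or counts on any inconsistency."""
    for p in (stack_path, te_path, roi_path) + ((reference_path,) if reference_path else ()):
        if not Path(p).exists():
            raise InputError(f"missing input file: {p}")
    data = np.asanyarray(nib.load(str(stack_path)).dataobj).astype(float)
    if data.ndim != 3:
        raise InputError(f"stack must be 3D (rows x cols x echoes); got shape {data.shape}")
    sidecar = yaml.safe_load(Path(te_path).read_text())
    if not isinstance(sidecar, dict) or "te_ms" not in sidecar:
        raise InputError(f"TE sidecar {te_path} must contain a 'te_ms' list")
    te_ms = np.asarray(sidecar["te_ms"], dtype=float)
    if len(te_ms) != data.shape[2]:
        raise InputError(
            f"TE sidecar lists {len(te_ms)} echo times for {data.shape[2]} echoes")
    stack = MultiEchoStack(echoes=np.moveaxis(data, -1, 0), te_ms=te_ms)

    roi_labels = np.asanyarray(nib.load(str(roi_path)).dataobj)
    if roi_labels.shape != stack.shape:
        raise InputError(f"ROI shape {roi_labels.shape} != stack image shape {stack.shape}")
    roi = roi_labels > 0

    reference = None
    if reference_path is not None:
        reference = read_mask(reference_path)
        if reference.labels.shape != stack.shape:
            raise InputError(
                f"reference shape {reference.labels.shape} != stack image shape {stack.shape}")
    return stack, roi, reference


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), _AFFINE), str(path))


def read_mask(path: str | Path, source: str = "manual") -> SegmentationMask:
    labels = np.asanyarray(nib.load(str(path)).dataobj).astype(np.uint8)
    if labels.ndim != 2:
        raise InputError(f"label map must be 2D; got shape {labels.shape}")
    if not set(np.unique(labels)) <= set(LABEL_ENCODING.values()):
        raise InputError("label map must use the 0/1/2 outside/parenchyma/vessel encoding")
    return SegmentationMask(labels=labels, source=source)


def write_map(scalar_map: ScalarMap, path: str | Path) -> None:
    data = np.where(scalar_map.valid_mask, scalar_map.values, np.nan)
    nib.save(nib.Nifti1Image(data.astype(np.float32), _AFFINE), str(path))


def read_map(path: str | Path) -> ScalarMap:
    values = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    return ScalarMap(values=values, valid_mask=np.isfinite(values))


def read_calibration(path: str | Path | None) -> LICCalibration:
    if path is None:
        return LICCalibration()
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        return LICCalibration(slope=float(cfg["slope"]), intercept=float(cfg["intercept"]))
    except (KeyError, TypeError) as exc:
        raise InputError(f"calibration file {path} must define slope and intercept") from exc


def _outcome_record(o: SchemeOutcome) -> dict:
    return {
        "method": o.method, "scheme": o.scheme, "te_index": o.te_index,
        "te_ms": o.te_ms, "u0": o.u0, "tsa_parenchyma_pct": o.tsa_parenchyma_pct,
        "tsa_vessels_pct": o.tsa_vessels_pct, "d_tsa_pct": o.d_tsa_pct,
        "selected_from": o.selected_from,
        "n_vessel_pixels": int(o.mask.vessel.sum()),
    }


def _gallery_panel(echo_img: np.ndarray, mask: SegmentationMask, path: Path) -> None:
    """One contact-sheet panel: the echo image with the candidate's vessel
    mask painted red."""
    lo, hi = float(echo_img.min()), float(echo_img.max())
    gray = np.zeros_like(echo_img) if hi == lo else (echo_img - lo) / (hi - lo)
    rgb = np.stack([gray] * 3, axis=-1)
    rgb[mask.vessel] = [1.0, 0.15, 0.15]
    Image.fromarray((rgb * 255).astype(np.uint8)).save(path)


def write_report(out_dir: str | Path, *, stack: MultiEchoStack,
                 op: OPResult | None = None, sa: SAResult | None = None,
                 summaries: dict | None = None,
                 calibration: LICCalibration = LICCalibration(),
                 extra: dict | None = None, gallery: bool = True) -> Path:
    """Write the machine-readable JSON report plus per-candidate CSV, label
    NIfTIs and (for SA) the PNG candidate gallery.  Idempotent: re-running
    on the same inputs reproduces the same bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "calibration": {"slope": calibration.slope, "intercept": calibration.intercept},
        "label_encoding": LABEL_ENCODING,
    }
    if extra:
        report.update(extra)
    if summaries:
        report["lic_summaries"] = {
            name: dataclasses.asdict(s) for name, s in summaries.items()}
        for s in report["lic_summaries"].values():
            s["level"] = s["level"].value

    if op is not None:
        op.candidates.to_csv(out / "op_candidates.csv", index=False,
                             float_format="%.4f")
        np.savez(out / "op_candidates_raw.npz",
                 d_tsa_pct=op.candidates["d_tsa_pct"].to_numpy(),
                 tsa_parenchyma_pct=op.candidates["tsa_parenchyma_pct"].to_numpy(),
                 tsa_vessels_pct=op.candidates["tsa_vessels_pct"].to_numpy())
        report["op"] = {
            "n_candidates": op.n_candidates,
            "candidates_csv": "op_candidates.csv",
            "best": {m: _outcome_record(o) for m, o in op.best.items()},
        }
        for name, o in (("op_1d", op.best_1d), ("op_2d", op.best_2d), ("op_mix", op.mix)):
            write_mask(o.mask, out / f"labels_{name}.nii")

    if sa is not None:
        import pandas as pd

        records = [_outcome_record(o)
                   for o in sa.candidates_1d + sa.candidates_2d]
        pd.DataFrame(records).to_csv(out / "sa_candidates.csv", index=False,
                                     float_format="%.4f")
        report["sa"] = {
            "te_index": sa.te_index,
            "te_ms": float(stack.te_ms[sa.te_index]),
            "rnr": [float(v) for v in sa.profile.rnr],
            "noise_sd": [float(v) for v in sa.profile.noise_sd],
            "n_candidates": {"1D-FCM": len(sa.candidates_1d),
                             "2D-FCM": len(sa.candidates_2d)},
            "candidates_csv": "sa_candidates.csv",
            "chosen": _outcome_record(sa.chosen) if sa.chosen else None,
        }
        if sa.chosen is not None:
            write_mask(sa.chosen.mask, out / "labels_sa_mix.nii")
        if gallery:
            gal = out / "sa_gallery"
            gal.mkdir(exist_ok=True)
            echo_img = stack.echoes[sa.te_index]
            for mode, cands in (("1D", sa.candidates_1d), ("2D", sa.candidates_2d)):
                for i, o in enumerate(cands):
                    _gallery_panel(echo_img, o.mask, gal / f"sa_{mode}_{i:02d}.png")

    _write_json(out / "report.json", report)
    return out / "report.json"
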