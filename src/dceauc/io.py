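"""NIfTI / CSV / JSON input-output for pipeline artifacts.

Image geometry travels through the NIfTI affine; frame timing and
acquisition parameters (TR, flip angles, relaxivity, baseline frames) live
in a JSON sidecar next to each image, since NIfTI headers cannot carry them
faithfully.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import ConcentrationSeries, DynamicSeries, T1Map, VFAScanPair

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_dynamic_series",
    "load_dynamic_series",
    "save_vfa_pair",
    "load_vfa_pair",
    "save_t1_map",
    "load_t1_map",
    "save_concentration",
    "load_concentration",
    "save_mask",
    "load_mask",
    "save_aif_csv",
    "load_aif_csv",
    "save_json",
    "load_json",
]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_nifti(data: np.ndarray, affine: np.ndarray, path, meta: dict | None = None) -> None:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
    if meta is not None:
        save_json(meta, _sidecar(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    img = nib.load(str(path))
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = load_json(side)
    return np.asarray(img.get_fdata()), np.asarray(img.affine), meta


def save_dynamic_series(series: DynamicSeries, path) -> None:
    save_nifti(series.data, series.affine, path, {"times_s": series.times_s})


def load_dynamic_series(path) -> DynamicSeries:
    data, affine, meta = load_nifti(path)
    if "times_s" not in meta:
        raise ValueError(f"sidecar of {path} must record times_s")
    return DynamicSeries(data=data, times_s=np.asarray(meta["times_s"]), affine=affine)


def save_vfa_pair(pair: VFAScanPair, path_low, path_high) -> None:
    meta = {"flip_angles_deg": pair.flip_angles_deg, "tr_s": pair.tr_s}
    save_nifti(pair.volumes[0], pair.affine, path_low, {**meta, "index": 0})
    save_nifti(pair.volumes[1], pair.affine, path_high, {**meta, "index": 1})


def load_vfa_pair(path_low, path_high) -> VFAScanPair:
    v0, affine, meta = load_nifti(path_low)
    v1, _, _ = load_nifti(path_high)
    return VFAScanPair(
        volumes=(v0, v1),
        flip_angles_deg=tuple(meta.get("flip_angles_deg", (6.0, 16.0))),
        tr_s=float(meta.get("tr_s", 0.005)),
        affine=affine,
    )


def save_t1_map(t1map: T1Map, path) -> None:
    save_nifti(t1map.t1_s, t1map.affine, path, {"n_valid": int(t1map.valid.sum())})
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    save_nifti(t1map.m0, t1map.affine, base + "_m0.nii.gz")
    save_nifti(t1map.valid.astype(float), t1map.affine, base + "_valid.nii.gz")


def load_t1_map(path) -> T1Map:
    t1, affine, _ = load_nifti(path)
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    m0, _, _ = load_nifti(base + "_m0.nii.gz")
    valid, _, _ = load_nifti(base + "_valid.nii.gz")
    return T1Map(t1_s=t1, m0=m0, valid=valid > 0.5, affine=affine)


def save_concentration(conc: ConcentrationSeries, path, extra_meta: dict | None = None) -> None:
    meta = {
        "times_s": conc.times_s,
        "baseline_frames": conc.baseline_frames,
        "n_inversion_failures": conc.n_inversion_failures,
    }
    if extra_meta:
        meta.update(extra_meta)
    save_nifti(conc.conc, conc.affine, path, meta)


def load_concentration(path) -> ConcentrationSeries:
    data, affine, meta = load_nifti(path)
    return ConcentrationSeries(
        conc=data,
        times_s=np.asarray(meta["times_s"]),
        baseline_frames=np.asarray(meta["baseline_frames"]),
        affine=affine,
        n_inversion_failures=int(meta.get("n_inversion_failures", 0)),
    )


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    save_nifti(mask.astype(np.float64), affine, path)


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    data, affine, _ = load_nifti(path)
    return data > 0.5, affine


def save_aif_csv(times_s, conc, path) -> None:
    pd.DataFrame({"time_s": times_s, "concentration_mmol_per_l": conc}).to_csv(
        path, index=False
    )


def load_aif_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (
        df["time_s"].to_numpy(dtype=float),
        df["concentration_mmol_per_l"].to_numpy(dtype=float),
    )
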