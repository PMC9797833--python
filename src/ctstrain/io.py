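"""File formats: NIfTI label volumes, JSON plane/threshold files, CSV
tables for expert labels, ground truth and results."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomTruth
from .reslicing import CineSegmentation, PlaneDefinition


# ---------------------------------------------------------------------------
# NIfTI cine volumes


def save_cine(cine: CineSegmentation, out: str | Path, single_4d: bool = True):
    """Write the cine segmentation as one 4D NIfTI or one 3D file per
    phase (``phase_XX.nii.gz``)."""
    out = Path(out)
    if single_4d:
        data = np.stack(cine.frames, axis=-1).astype(np.uint8)
        nib.save(nib.Nifti1Image(data, cine.affine), str(out))
        return [out]
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(cine.frames):
        p = out / f"phase_{t:02d}.nii.gz"
        nib.save(nib.Nifti1Image(frame.astype(np.uint8), cine.affine), str(p))
        paths.append(p)
    return paths


def load_cine(paths) -> CineSegmentation:
    """Read a cine segmentation from a single 4D NIfTI or a sorted list
    of per-phase 3D NIfTIs, honouring the file affine."""
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        data = np.asarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"{paths}: expected a 4D volume, got {data.ndim}D")
        frames = [np.rint(data[..., t]).astype(np.uint8)
                  for t in range(data.shape[-1])]
        return CineSegmentation(frames=frames, affine=img.affine)
    paths = sorted(Path(p) for p in paths)
    frames, affine = [], None
    for p in paths:
        img = nib.load(str(p))
        if affine is None:
            affine = img.affine
        elif not np.allclose(img.affine, affine, atol=1e-4):
            raise ValueError(f"{p}: affine differs from first phase")
        frames.append(np.rint(np.asarray(img.dataobj)).astype(np.uint8))
    return CineSegmentation(frames=frames, affine=affine)


# ---------------------------------------------------------------------------
# plane definitions / thresholds (JSON)


def save_planes(planes, path: str | Path):
    payload = [
        {
            "view": p.view,
            "origin_mm": list(map(float, p.origin_mm)),
            "x_dir": list(map(float, p.x_dir)),
            "y_dir": list(map(float, p.y_dir)),
        }
        for p in planes
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_planes(path: str | Path):
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed plane JSON: {e}") from e
    planes = []
    for i, item in enumerate(payload):
        for key in ("view", "origin_mm", "x_dir", "y_dir"):
            if key not in item:
                raise ValueError(f"{path}: plane {i} missing field {key!r}")
        planes.append(
            PlaneDefinition(
                view=item["view"],
                origin_mm=np.array(item["origin_mm"], dtype=float),
                x_dir=np.array(item["x_dir"], dtype=float),
                y_dir=np.array(item["y_dir"], dtype=float),
            )
        )
    return planes


def save_thresholds(thresholds: dict, path: str | Path):
    """Thresholds file: {"mode": "individual"|"single", "tau": {...}|float}."""
    Path(path).write_text(json.dumps(thresholds, indent=2))


def load_thresholds(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# CSV tables


def save_truth(truth: PhantomTruth, path: str | Path):
    rows = []
    for view, per in truth.perimeter_mm.items():
        for t, p in enumerate(per):
            rows.append(
                {
                    "view": view,
                    "phase": t,
                    "perimeter_mm": p,
                    "ls": truth.ls[view],
                    "fac": truth.fac[view],
                    "ef": truth.ef,
                    "ed": truth.ed_phase,
                    "es": truth.es_phase,
                    "abnormal_view": truth.abnormal_view[view],
                    "abnormal_study": truth.abnormal_study,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_contour_csv(contour, path: str | Path):
    """Write an EndoContour as an ordered (x_mm, y_mm) point list."""
    df = pd.DataFrame(contour.points_mm, columns=["x_mm", "y_mm"])
    df.insert(0, "method", contour.method)
    df.to_csv(path, index=False)


def load_contour_csv(path: str | Path):
    from .contouring import EndoContour

    df = pd.read_csv(path)
    return EndoContour(df[["x_mm", "y_mm"]].to_numpy(),
                       method=str(df["method"].iloc[0]))


def load_expert_labels(path: str | Path) -> dict:
    """Expert label CSV (study, reader, segment, label) ->
    {study: {reader: {segment: label}}}."""
    df = pd.read_csv(path)
    need = {"study", "reader", "segment", "label"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out: dict = {}
    for row in df.itertuples():
        out.setdefault(row.study, {}).setdefault(row.reader, {})[
            int(row.segment)
        ] = str(row.label)
    return out


def save_expert_labels(labels: dict, path: str | Path):
    rows = [
        {"study": s, "reader": r, "segment": seg, "label": lab}
        for s, readers in labels.items()
        for r, segs in readers.items()
        for seg, lab in segs.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def results_frame(study_results: dict) -> pd.DataFrame:
    """Flatten {study: StrainResult} into the long results table."""
    rows = []
    for study, res in study_results.items():
        for view, per_method in res.ls.items():
            for method, ls in per_method.items():
                rows.append(
                    {
                        "study": study,
                        "view": view,
                        "method": method,
                        "ls": ls,
                        "fac": res.fac[view],
                        "ef": res.ef,
                        "ed": res.ed,
                        "es": res.es,
                        "compliant": res.compliant.get(view, True),
                    }
                )
    return pd.DataFrame(rows).sort_values(
        ["study", "view", "method"], kind="stable"
    ).reset_index(drop=True)
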