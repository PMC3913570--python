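"""File formats: phantom text serialization, evaluation reports, NIfTI volumes."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .experiments import EvalReport, REPORT_COLUMNS
from .phantom import AcquisitionParams, AifModelParams, PhantomDataset, TissueClassParams, true_aif_curve

__all__ = [
    "save_phantom",
    "load_phantom",
    "phantom_to_nifti",
    "read_4d_image",
    "write_report",
    "read_report",
]

DEFAULT_CLINICAL_DT = 1.5  # s, repetition time fallback when the header lacks one


def save_phantom(ds: PhantomDataset, curves_path, sidecar_path) -> None:
    """Write voxel curves as delimited text plus a YAML parameter sidecar.

    One row per voxel: the class label then the signal samples. The sidecar
    records every parameter and the seed, enough to rebuild the dataset.
    """
    df = pd.DataFrame(ds.curves)
    df.insert(0, "label", ds.labels)
    df.to_csv(curves_path, sep="\t", index=False)

    meta = {
        "seed": ds.seed,
        "aif_params": asdict(ds.aif_params),
        "acquisition": asdict(ds.acq),
        "tissue_classes": [asdict(c) for c in ds.tissue_classes],
    }
    Path(sidecar_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_phantom(curves_path, sidecar_path) -> PhantomDataset:
    """Inverse of :func:`save_phantom`; the true AIF is rebuilt from the stored parameters."""
    meta = yaml.safe_load(Path(sidecar_path).read_text())
    aif_params = AifModelParams(**meta["aif_params"])
    acq = AcquisitionParams(**meta["acquisition"])
    classes = tuple(TissueClassParams(**c) for c in meta["tissue_classes"])

    df = pd.read_csv(curves_path, sep="\t")
    labels = df["label"].to_numpy(dtype=object)
    curves = df.drop(columns="label").to_numpy(dtype=float)
    times = acq.grid()
    return PhantomDataset(
        times=times,
        curves=curves,
        labels=labels,
        true_aif=true_aif_curve(times, aif_params),
        seed=int(meta["seed"]),
        aif_params=aif_params,
        acq=acq,
        tissue_classes=classes,
    )


def phantom_to_nifti(ds: PhantomDataset, path) -> None:
    """Export the phantom as a 4D NIfTI: x = voxel index, single row/slice, t = frames."""
    data = ds.curves[:, None, None, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ds.acq.dt))
    nib.save(img, str(path))


def read_4d_image(path) -> tuple[np.ndarray, float]:
    """Load a 4D NIfTI volume; returns the (x, y, slice, time) array and the frame spacing.

    The time step comes from the header's fourth zoom; a missing or
    nonpositive value falls back to 1.5 s.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4-D NIfTI volume, got {img.ndim} dimensions")
    zooms = img.header.get_zooms()
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else DEFAULT_CLINICAL_DT
    return np.asarray(img.get_fdata(), dtype=float), dt


def write_report(report: EvalReport, path) -> None:
    """Evaluation table as CSV: columns PVE,PV,TTP,FWHM,AUC,RMSE,M at 4 decimals."""
    report.table.to_csv(path, float_format="%.4f")


def read_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report is missing columns: {missing}")
    return df
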