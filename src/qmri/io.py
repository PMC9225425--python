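"""NIfTI and tabular I/O for phantom and derived volumes."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .phantom import AcquisitionSpec, DceSeries, MultiEchoStack, RoiMaskSet

__all__ = [
    "save_volume",
    "save_multi_echo",
    "save_dce",
    "save_labels",
    "load_multi_echo",
    "load_dce",
    "load_labels",
]


def _affine(voxel_size_um: Sequence[float]) -> np.ndarray:
    return np.diag([voxel_size_um[0] / 1000.0, voxel_size_um[1] / 1000.0,
                    voxel_size_um[2] / 1000.0, 1.0])


def save_volume(data: np.ndarray, path, voxel_size_um=(150.0, 150.0, 1000.0),
                dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), _affine(voxel_size_um))
    nib.save(img, str(path))


def save_multi_echo(stack: MultiEchoStack, path, acq: AcquisitionSpec) -> None:
    """4D NIfTI, 4th axis = echo; echo times stored in the header description."""
    img = nib.Nifti1Image(stack.data.astype(np.float32), _affine(acq.voxel_size_um))
    img.header["descrip"] = ("TE_ms=" + ",".join(f"{t:g}" for t in
                                                 stack.echo_times_ms)).encode()[:79]
    nib.save(img, str(path))


def save_dce(series: DceSeries, path, acq: AcquisitionSpec) -> None:
    """4D NIfTI, 4th axis = frame; frame duration carried in pixdim[4]."""
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(acq.voxel_size_um))
    img.header["pixdim"][4] = series.frame_duration_min
    nib.save(img, str(path))


def save_labels(rois: RoiMaskSet, path, acq: AcquisitionSpec) -> None:
    img = nib.Nifti1Image(rois.labels.astype(np.int16), _affine(acq.voxel_size_um))
    nib.save(img, str(path))


def load_multi_echo(path, echo_times_ms: Sequence[float]) -> MultiEchoStack:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D multi-echo stack")
    return MultiEchoStack(data=data, echo_times_ms=np.asarray(echo_times_ms, float))


def load_dce(path, frame_duration_min: float = 1.0,
             injection_start_min: float = 2.0) -> DceSeries:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D DCE series")
    n = data.shape[-1]
    mids = (np.arange(n) + 0.5) * frame_duration_min
    return DceSeries(data=data, frame_times_min=mids,
                     frame_duration_min=frame_duration_min,
                     injection_start_min=injection_start_min)


def load_labels(path, names: Optional[Sequence[str]] = None) -> RoiMaskSet:
    """Load an integer label volume; ``names`` maps label order (label i+1 ->
    names[i]); defaults to generic ``roi_<label>`` names."""
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    present = sorted(int(v) for v in np.unique(labels) if v != 0)
    if names is not None:
        label_map = {name: i + 1 for i, name in enumerate(names) if i + 1 in present}
    else:
        label_map = {f"roi_{v}": v for v in present}
    return RoiMaskSet(labels=labels, label_map=label_map)
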