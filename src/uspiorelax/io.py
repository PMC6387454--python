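"""NIfTI volume I/O with sidecar metadata.

Each acquisition is stored as a NIfTI-1 volume plus a JSON sidecar holding
the sequence parameters and the scanner intensity scale factor — the two
pieces of metadata the fitting stages need and NIfTI headers cannot carry.
Sidecars live next to the volume with the ``.json`` extension
(``stack.nii.gz`` → ``stack.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .sequences import SequenceParams

__all__ = [
    "ImageStack",
    "CongruenceError",
    "SidecarError",
    "read_volume",
    "write_volume",
    "read_map",
    "write_map",
    "check_congruent",
]

SENTINEL = np.nan  # value written for voxels that could not be fitted


class SidecarError(FileNotFoundError):
    """Missing or malformed sidecar JSON."""


class CongruenceError(ValueError):
    """Volumes that should share a grid/affine do not."""


@dataclass
class ImageStack:
    """A signal volume, its acquisition parameters and intensity scale.

    ``data`` is 3-D, or 4-D with echoes on the last axis (multi-echo).  The
    ``scale`` is the multiplicative intensity factor imposed by the scanner;
    :meth:`corrected` undoes it, which is the first step of every fit.
    """

    data: np.ndarray
    seq: SequenceParams
    scale: float = 1.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def corrected(self) -> np.ndarray:
        """Signal corrected for the scanner intensity scaling."""
        return np.asarray(self.data, dtype=float) / self.scale

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return p.with_name(name[: -len(ext)] + ".json")
    return p.with_suffix(".json")


def write_volume(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as float32 NIfTI-1 plus its JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(stack.data, dtype=np.float32), stack.affine)
    nib.save(img, str(path))
    sidecar = {"sequence": stack.seq.to_dict(), "scale": stack.scale}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> ImageStack:
    """Read a NIfTI volume and its sidecar into an :class:`ImageStack`.

    NIfTI ``scl_slope``/``scl_inter`` header scaling is honoured (applied by
    nibabel's ``get_fdata``).  A missing sidecar raises :class:`SidecarError`
    naming the expected fields.
    """
    path = Path(path)
    img = nib.load(str(path))
    sc = _sidecar_path(path)
    if not sc.exists():
        raise SidecarError(
            f"sidecar {sc} not found; expected JSON with fields "
            "'sequence' (SequenceParams dict) and 'scale' (float)"
        )
    meta = json.loads(sc.read_text())
    if "sequence" not in meta:
        raise SidecarError(f"sidecar {sc} lacks the 'sequence' field")
    seq = SequenceParams.from_dict(meta["sequence"])
    return ImageStack(
        data=np.asarray(img.get_fdata(), dtype=float),
        seq=seq,
        scale=float(meta.get("scale", 1.0)),
        affine=img.affine,
    )


def write_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a float32 parameter map (units s⁻¹ for rates, unitless for k)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def check_congruent(*items, atol: float = 1e-4) -> None:
    """Require identical grids and affines across stacks / (map, affine) pairs.

    Accepts :class:`ImageStack` objects or ``(array, affine)`` tuples.
    Registration is out of scope, so congruence is a hard precondition.
    """
    shapes, affines = [], []
    for it in items:
        if isinstance(it, ImageStack):
            shapes.append(it.shape3)
            affines.append(it.affine)
        else:
            arr, aff = it
            shapes.append(tuple(np.shape(arr)[:3]))
            affines.append(aff)
    if len(set(shapes)) > 1:
        raise CongruenceError(f"grid shapes differ: {shapes}")
    for aff in affines[1:]:
        if not np.allclose(affines[0], aff, atol=atol):
            raise CongruenceError("affines differ; volumes are not co-registered")
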