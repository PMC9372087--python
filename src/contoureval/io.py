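"""Reading, writing and resampling of volumetric grids (NIfTI / NRRD).

SimpleITK handles the file formats; arrays are transposed between ITK's
(z, y, x) memory order and this package's (x, y, z) convention. Direction
matrices other than identity are not supported — phantom and evaluation
grids are axis-aligned by construction.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grids import BinaryMask, Geometry, GeometryError, StructureSet, VolumeGrid

log = logging.getLogger(__name__)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr")


class FormatError(ValueError):
    """The file is not a supported volumetric format."""


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format: {path.name!r} (expected one of {_SUPPORTED_SUFFIXES})"
        )


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    """Write a grid to NIfTI or NRRD, preserving spacing and origin."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def write_labelmap(sset: StructureSet, path: str | Path, names: list[str] | None = None) -> None:
    """Write a structure set as an integer labelmap volume (k = k-th name)."""
    labels = sset.to_labelmap(names)
    g = sset.geometry
    write_volume(VolumeGrid(labels, g.spacing, g.origin), path)


def read_volume(
    path: str | Path,
    kind: str = "image",
    structure_names: list[str] | None = None,
    provenance: str = "manual",
) -> VolumeGrid | StructureSet:
    """Read a volume from disk.

    Parameters
    ----------
    kind
        ``image`` or ``dose`` return a :class:`VolumeGrid`; ``labelmap``
        splits integer label k > 0 into the k-th entry of *structure_names*
        and returns a :class:`StructureSet`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    if kind not in ("image", "dose", "labelmap"):
        raise ValueError(f"kind must be image, dose or labelmap, got {kind!r}")

    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T  # (x, y, z)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    grid = VolumeGrid(values, spacing, origin)
    if kind != "labelmap":
        return grid

    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError(f"labelmap {path.name} contains non-integer values")
        values = np.round(values).astype(np.int32)
    if values.min() < 0:
        raise ValueError(f"labelmap {path.name} contains negative labels")
    labels = sorted(int(v) for v in np.unique(values) if v > 0)
    if structure_names is None:
        structure_names = [f"structure_{k}" for k in labels]
    geom = grid.geometry
    structures = {}
    for k in labels:
        if k > len(structure_names):
            raise ValueError(
                f"label {k} exceeds the {len(structure_names)} configured structure names"
            )
        structures[structure_names[k - 1]] = BinaryMask(geom, values == k)
    return StructureSet(structures, provenance=provenance)


def resample_to(src: VolumeGrid, ref: Geometry | VolumeGrid, mode: str = "trilinear") -> VolumeGrid:
    """Resample *src* onto the lattice of *ref*.

    ``trilinear`` is for dose/image fields, ``nearest`` for label data.
    Voxels of the reference outside the source extent are filled with 0
    (with a warning): partial coverage is treated as zero dose.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"mode must be 'trilinear' or 'nearest', got {mode!r}")
    ref_geom = ref.geometry if isinstance(ref, VolumeGrid) else ref

    src_lo, src_hi = src.geometry.extent()
    ref_lo, ref_hi = ref_geom.extent()
    if np.any(ref_lo > src_hi) or np.any(ref_hi < src_lo):
        raise GeometryError("source and reference grids have no physical overlap")

    if src.geometry.matches(ref_geom):
        return VolumeGrid(src.values.copy(), ref_geom.spacing, ref_geom.origin)

    # reference voxel centers expressed in fractional source index space
    axes = [
        (ref_geom.origin[d] + np.arange(ref_geom.shape[d]) * ref_geom.spacing[d] - src.geometry.origin[d])
        / src.geometry.spacing[d]
        for d in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    order = 1 if mode == "trilinear" else 0
    out = ndimage.map_coordinates(
        src.values.astype(float), np.stack(coords), order=order, mode="constant", cval=0.0
    )
    if np.any(ref_lo < src_lo - 1e-9) or np.any(ref_hi > src_hi + 1e-9):
        warnings.warn(
            "reference grid extends beyond source extent; out-of-extent voxels filled with 0",
            stacklevel=2,
        )
    if mode == "nearest" and src.values.dtype == bool:
        out = out.astype(bool)
    return VolumeGrid(out, ref_geom.spacing, ref_geom.origin)
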