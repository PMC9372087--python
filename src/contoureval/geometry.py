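"""Contour-overlap and surface-distance metrics.

Dice similarity coefficient (DSC), Jaccard coefficient (JC), and the
Hausdorff distance family (classic maximum and percentile variants such
as the 95% Hausdorff distance) between two binary segmentations of the
same lattice. All distances are Euclidean in physical millimetres, so
anisotropic slice spacing is respected.

Conventions (stated so an exhaustive all-pairs oracle is bit-comparable):

* A *surface voxel* is a foreground voxel with at least one background
  6-neighbor; the volume border counts as background. Surface points are
  voxel centers in physical mm.
* The directed distance from set A to set B takes, for every surface
  point of B, the minimum distance to A's surface; the percentile-p
  directed value is the p-th percentile (linear interpolation between
  order statistics) of that distribution, with p=100 reproducing the
  classic directed maximum. The symmetric result is the larger of the
  two directed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import BinaryMask, EmptyStructureError, GeometryError, StructureSet


@dataclass(frozen=True)
class SurfacePointSet:
    """Physical-coordinate centers (mm) of a structure's boundary voxels."""

    points: np.ndarray  # (N, 3) float
    structure: str = ""


@dataclass(frozen=True)
class GeometricMetrics:
    structure: str
    dsc: float
    jc: float
    hd_mm: float
    hd95_mm: float


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if not a.geometry.matches(b.geometry):
        raise GeometryError("masks must share grid geometry")


def extract_surface(mask: BinaryMask) -> SurfacePointSet:
    """Boundary voxels of *mask* (6-connectivity, border = outside) as mm points."""
    if mask.is_empty():
        raise EmptyStructureError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(mask.voxels, structure=_SIX_CONN, border_value=0)
    surface = mask.voxels & ~interior
    pts = mask.geometry.indices_to_physical(np.argwhere(surface))
    return SurfacePointSet(points=pts)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """DSC = 2|A∩B| / (|A| + |B|)."""
    _check_pair(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise EmptyStructureError("DSC is undefined for two empty masks")
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """JC = |A∩B| / |A∪B|."""
    _check_pair(a, b)
    if a.n_voxels == 0 and b.n_voxels == 0:
        raise EmptyStructureError("JC is undefined for two empty masks")
    inter = int((a.voxels & b.voxels).sum())
    union = int((a.voxels | b.voxels).sum())
    return inter / union


def hausdorff(a: BinaryMask, b: BinaryMask, percentile: float = 100.0) -> float:
    """(Percentile) Hausdorff distance between the surfaces of A and B, in mm."""
    _check_pair(a, b)
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    if a.is_empty() or b.is_empty():
        raise EmptyStructureError("Hausdorff distance requires two non-empty masks")
    pa = extract_surface(a).points
    pb = extract_surface(b).points
    d_to_a = cKDTree(pa).query(pb)[0]  # one value per point of B
    d_to_b = cKDTree(pb).query(pa)[0]
    ha = float(np.percentile(d_to_a, percentile))
    hb = float(np.percentile(d_to_b, percentile))
    return max(ha, hb)


def compute_metrics(ref: BinaryMask, test: BinaryMask, structure: str = "") -> GeometricMetrics:
    """DSC, JC, HD and 95%HD for one reference/test mask pair."""
    return GeometricMetrics(
        structure=structure,
        dsc=dice(ref, test),
        jc=jaccard(ref, test),
        hd_mm=hausdorff(ref, test, 100.0),
        hd95_mm=hausdorff(ref, test, 95.0),
    )


def evaluate_geometry(ref: StructureSet, test: StructureSet) -> pd.DataFrame:
    """Per-structure geometric metrics between a reference and a test set.

    Structures present in only one set are reported with status
    ``missing_in_test`` / ``missing_in_ref`` rather than dropped; masks are
    compared whole, never cropped. Raises if the sets share no structure.
    """
    common = [n for n in ref.names() if n in test]
    if not common:
        raise ValueError("structure sets share no common structure names")
    rows = []
    for name in ref.names():
        if name in test:
            if ref[name].is_empty() or test[name].is_empty():
                rows.append(
                    dict(structure=name, dsc=np.nan, jc=np.nan, hd_mm=np.nan,
                         hd95_mm=np.nan, status="empty")
                )
                continue
            m = compute_metrics(ref[name], test[name], name)
            rows.append(
                dict(structure=name, dsc=m.dsc, jc=m.jc, hd_mm=m.hd_mm,
                     hd95_mm=m.hd95_mm, status="ok")
            )
        else:
            rows.append(
                dict(structure=name, dsc=np.nan, jc=np.nan, hd_mm=np.nan,
                     hd95_mm=np.nan, status="missing_in_test")
            )
    for name in test.names():
        if name not in ref:
            rows.append(
                dict(structure=name, dsc=np.nan, jc=np.nan, hd_mm=np.nan,
                     hd95_mm=np.nan, status="missing_in_ref")
            )
    return pd.DataFrame(rows)
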