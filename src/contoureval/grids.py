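"""Volumetric data model: scalar grids, binary masks, structure sets, plan config.

All arrays are indexed (x, y, z) with the physical position of voxel
``(i, j, k)`` given by ``origin + index * spacing`` (voxel-center
convention, 0-based). Spacing is anisotropic, in millimetres; dose values
are in cGy throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

#: Planning-structure names evaluated by the pipeline (target + organs at risk).
STRUCTURE_NAMES = (
    "CTV",
    "Spinal Cord",
    "Kidney L",
    "Kidney R",
    "Bladder",
    "Femoral Head L",
    "Femoral Head R",
    "Pelvic Bone",
    "Rectum",
)

GEOM_TOL_MM = 1e-6


class GeometryError(ValueError):
    """Grid geometries are incompatible for the requested operation."""


class EmptyStructureError(ValueError):
    """An operation that needs a non-empty mask received an empty one."""


@dataclass(frozen=True)
class Geometry:
    """Shape, spacing (mm) and origin (mm) of a 3D voxel lattice."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise GeometryError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def matches(self, other: "Geometry", tol: float = GEOM_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def indices_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to physical mm coordinates."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box of voxel centers: (low corner, high corner)."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class VolumeGrid:
    """A 3D scalar field (CT intensity or dose in cGy) on a regular lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"values must be 3D, got ndim={self.values.ndim}")
        # validates spacing/origin
        self._geometry = Geometry(self.values.shape, self.spacing, self.origin)
        self.spacing = self._geometry.spacing
        self.origin = self._geometry.origin

    @property
    def geometry(self) -> Geometry:
        return self._geometry


@dataclass
class BinaryMask:
    """A named-structure occupancy mask sharing a grid geometry."""

    geometry: Geometry
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {self.voxels.shape} != grid shape {self.geometry.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.geometry.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class StructureSet:
    """Named binary masks on one shared grid, tagged manual or auto."""

    structures: dict[str, BinaryMask]
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.provenance not in ("manual", "auto"):
            raise ValueError(f"provenance must be 'manual' or 'auto', got {self.provenance!r}")
        geoms = [m.geometry for m in self.structures.values()]
        for g in geoms[1:]:
            if not g.matches(geoms[0]):
                raise GeometryError("all masks in a StructureSet must share one geometry")

    @property
    def geometry(self) -> Geometry:
        if not self.structures:
            raise ValueError("empty structure set has no geometry")
        return next(iter(self.structures.values())).geometry

    def names(self) -> list[str]:
        return list(self.structures)

    def __getitem__(self, name: str) -> BinaryMask:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def __iter__(self) -> Iterator[str]:
        return iter(self.structures)

    def to_labelmap(self, names: list[str] | None = None) -> np.ndarray:
        """Integer labelmap; label k corresponds to names[k-1], 0 = background.

        Later structures overwrite earlier ones where masks overlap.
        """
        names = list(self.structures) if names is None else names
        out = np.zeros(self.geometry.shape, dtype=np.int16)
        for k, name in enumerate(names, start=1):
            if name in self.structures:
                out[self.structures[name].voxels] = k
        return out


# ---------------------------------------------------------------------------
# Plan configuration and dose constraints


@dataclass(frozen=True)
class Constraint:
    """One planning dose constraint, e.g. D_50% < 100% of prescription.

    metric uses the planning shorthand: ``Dmean``, ``Dmax``, ``D99%``,
    ``D50%``, ``D30%``, ``D15%``, ``D0.03cc``, ``V100%``.
    limit_pct_rx expresses the bound as a percentage of the prescription;
    limit_cGy is an absolute bound. Exactly one must be set.
    """

    structure: str
    metric: str
    direction: str  # "<" or ">"
    limit_cGy: float | None = None
    limit_pct_rx: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("<", ">"):
            raise ValueError(f"direction must be '<' or '>', got {self.direction!r}")
        if (self.limit_cGy is None) == (self.limit_pct_rx is None):
            raise ValueError("exactly one of limit_cGy / limit_pct_rx must be set")

    def bound_cGy(self, prescription_cGy: float) -> float:
        if self.limit_cGy is not None:
            return self.limit_cGy
        return self.limit_pct_rx / 100.0 * prescription_cGy

    def check(self, value: float, prescription_cGy: float) -> bool:
        bound = self.bound_cGy(prescription_cGy)
        return value < bound if self.direction == "<" else value > bound

    def label(self) -> str:
        if self.limit_cGy is not None:
            return f"{self.metric} {self.direction} {self.limit_cGy:g} cGy"
        return f"{self.metric} {self.direction} {self.limit_pct_rx:g}%Rx"


def default_constraints() -> list[Constraint]:
    """The external-beam planning constraint set for the nine pelvic structures."""
    c = Constraint
    return [
        c("CTV", "D99%", ">", limit_pct_rx=100.0),
        c("CTV", "Dmax", "<", limit_pct_rx=110.0),
        c("Spinal Cord", "Dmax", "<", limit_cGy=4000.0),
        c("Kidney L", "Dmean", "<", limit_cGy=1200.0),
        c("Kidney R", "Dmean", "<", limit_cGy=1200.0),
        c("Bladder", "D50%", "<", limit_pct_rx=100.0),
        c("Bladder", "D0.03cc", "<", limit_pct_rx=110.0),
        c("Femoral Head L", "D15%", "<", limit_cGy=3000.0),
        c("Femoral Head L", "Dmean", "<", limit_cGy=2000.0),
        c("Femoral Head R", "D15%", "<", limit_cGy=3000.0),
        c("Femoral Head R", "Dmean", "<", limit_cGy=2000.0),
        c("Pelvic Bone", "Dmean", "<", limit_cGy=3000.0),
        c("Rectum", "D50%", "<", limit_pct_rx=100.0),
        c("Rectum", "D0.03cc", "<", limit_pct_rx=110.0),
    ]


#: Dose metric(s) of record per structure for the paired manual/auto comparison.
METRICS_OF_RECORD: Mapping[str, tuple[str, ...]] = {
    "CTV": ("Dmean", "V100%"),
    "Spinal Cord": ("Dmax",),
    "Kidney L": ("Dmean",),
    "Kidney R": ("Dmean",),
    "Bladder": ("Dmean",),
    "Femoral Head L": ("Dmean",),
    "Femoral Head R": ("Dmean",),
    "Pelvic Bone": ("Dmean",),
    "Rectum": ("Dmean",),
}


@dataclass
class PlanConfig:
    """Prescription and constraint set for one external-beam plan."""

    prescription_cGy: float = 5040.0
    fractions: int = 28
    constraints: list[Constraint] = field(default_factory=default_constraints)

    def __post_init__(self) -> None:
        if self.prescription_cGy <= 0:
            raise ValueError("prescription_cGy must be positive")
        if self.fractions < 1:
            raise ValueError("fractions must be a positive integer")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "prescription_cGy": self.prescription_cGy,
            "fractions": self.fractions,
            "constraints": [dataclasses.asdict(c) for c in self.constraints],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanConfig":
        payload = json.loads(Path(path).read_text())
        cons = [Constraint(**c) for c in payload.get("constraints", [])]
        return cls(
            prescription_cGy=payload["prescription_cGy"],
            fractions=payload["fractions"],
            constraints=cons or default_constraints(),
        )
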