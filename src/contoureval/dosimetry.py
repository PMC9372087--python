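"""Dose–volume histograms and dose–volume indices (DVIs).

The cumulative DVH gives, for each dose level d, the percentage of a
structure's volume receiving at least d. Scalar indices are read off it:

* ``Dmean`` / ``Dmax`` — arithmetic mean / maximum of in-structure voxel
  doses, computed on voxels directly (not the binned curve).
* ``Dx%`` / ``Dx cc`` — minimum dose to the hottest x percent (or x cc)
  of the structure, by linear interpolation on the cumulative curve.
* ``Vd`` — percent of the structure receiving at least dose d, where d
  may be absolute cGy or a percentage of the prescription (V100% is the
  target-coverage index).

``evaluate_dosimetry`` recomputes the per-structure indices of record for
manual and auto contour sets against one fixed dose grid — the transmit-
into-original-plan protocol: the plan is never re-optimized for the auto
contours.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import (
    METRICS_OF_RECORD,
    BinaryMask,
    EmptyStructureError,
    GeometryError,
    PlanConfig,
    StructureSet,
    VolumeGrid,
)

DEFAULT_BIN_WIDTH_CGY = 1.0


@dataclass
class DVHCurve:
    """Cumulative dose–volume curve for one structure in one dose grid."""

    dose_edges: np.ndarray  # ascending, cGy
    cum_volume_pct: np.ndarray  # % of volume receiving >= edge
    volume_cc: float
    structure: str = ""


@dataclass
class DoseVolumeIndex:
    structure: str
    d_mean_cGy: float
    d_max_cGy: float
    extras: dict[str, float]  # e.g. {"V100%": 99.98, "D99%": 5102.3}

    def value(self, metric: str) -> float:
        if metric == "Dmean":
            return self.d_mean_cGy
        if metric == "Dmax":
            return self.d_max_cGy
        return self.extras[metric]


def _in_structure_doses(dose: VolumeGrid, mask: BinaryMask) -> np.ndarray:
    if not dose.geometry.matches(mask.geometry):
        raise GeometryError("dose grid and mask must share geometry (resample first)")
    if mask.is_empty():
        raise EmptyStructureError("DVH requires a non-empty structure")
    return dose.values[mask.voxels].astype(float)


def cumulative_dvh(
    dose: VolumeGrid, mask: BinaryMask, bin_width_cGy: float = DEFAULT_BIN_WIDTH_CGY,
    structure: str = "",
) -> DVHCurve:
    """Cumulative DVH of *mask* in *dose* with edges every *bin_width_cGy*."""
    if bin_width_cGy <= 0:
        raise ValueError("bin width must be positive")
    d = _in_structure_doses(dose, mask)
    top = float(d.max()) + bin_width_cGy
    edges = np.arange(0.0, top + bin_width_cGy, bin_width_cGy)
    # cumulative count of voxels with dose >= edge, exact at every edge
    cum = 100.0 * (d[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(edges, cum, volume_cc=mask.volume_cc, structure=structure)


def dose_at_volume(curve: DVHCurve, volume_pct: float | None = None,
                   volume_cc: float | None = None) -> float:
    """Minimum dose (cGy) to the hottest given volume, off the cumulative curve.

    Exactly one of *volume_pct* / *volume_cc* must be given. Linear
    interpolation between curve edges; the largest dose at which the
    cumulative volume still reaches the request.
    """
    if (volume_pct is None) == (volume_cc is None):
        raise ValueError("specify exactly one of volume_pct / volume_cc")
    if volume_cc is not None:
        if volume_cc > curve.volume_cc:
            raise ValueError(
                f"requested {volume_cc} cc exceeds structure volume {curve.volume_cc:.3f} cc"
            )
        volume_pct = 100.0 * volume_cc / curve.volume_cc
    if not 0.0 < volume_pct <= 100.0:
        raise ValueError(f"requested volume must be in (0, 100]%, got {volume_pct}")

    cum = curve.cum_volume_pct
    edges = curve.dose_edges
    # cum is non-increasing from 100; find the last edge with cum >= target,
    # then interpolate toward the next edge
    idx = np.nonzero(cum >= volume_pct)[0]
    i = idx[-1]
    if i == len(edges) - 1 or cum[i] == volume_pct:
        return float(edges[i])
    # interpolate on the descending segment [i, i+1]
    c0, c1 = cum[i], cum[i + 1]
    frac = (c0 - volume_pct) / (c0 - c1)
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def volume_at_dose(curve: DVHCurve, dose_cGy: float | None = None,
                   dose_pct_rx: float | None = None,
                   plan: PlanConfig | None = None) -> float:
    """Percent of the structure receiving at least the given dose."""
    if (dose_cGy is None) == (dose_pct_rx is None):
        raise ValueError("specify exactly one of dose_cGy / dose_pct_rx")
    if dose_pct_rx is not None:
        if plan is None:
            raise ValueError("a PlanConfig is required to resolve a %-of-prescription dose")
        dose_cGy = dose_pct_rx / 100.0 * plan.prescription_cGy
    if dose_cGy < 0:
        raise ValueError("dose must be non-negative")
    edges, cum = curve.dose_edges, curve.cum_volume_pct
    if dose_cGy <= edges[0]:
        return float(cum[0])
    if dose_cGy >= edges[-1]:
        return float(cum[-1])
    return float(np.interp(dose_cGy, edges, cum))


def mean_max_dose(dose: VolumeGrid, mask: BinaryMask) -> tuple[float, float]:
    """(mean, max) of in-structure voxel doses in cGy."""
    d = _in_structure_doses(dose, mask)
    return float(d.mean()), float(d.max())


_D_PCT = re.compile(r"^D(\d+(?:\.\d+)?)%$")
_D_CC = re.compile(r"^D(\d+(?:\.\d+)?)cc$")
_V_PCT = re.compile(r"^V(\d+(?:\.\d+)?)%$")


def metric_value(metric: str, dose: VolumeGrid, mask: BinaryMask, plan: PlanConfig,
                 bin_width_cGy: float = DEFAULT_BIN_WIDTH_CGY) -> float:
    """Evaluate one shorthand dose metric (Dmean, Dmax, D99%, D0.03cc, V100%...)."""
    if metric == "Dmean":
        return mean_max_dose(dose, mask)[0]
    if metric == "Dmax":
        return mean_max_dose(dose, mask)[1]
    curve = cumulative_dvh(dose, mask, bin_width_cGy)
    if m := _D_PCT.match(metric):
        return dose_at_volume(curve, volume_pct=float(m.group(1)))
    if m := _D_CC.match(metric):
        return dose_at_volume(curve, volume_cc=float(m.group(1)))
    if m := _V_PCT.match(metric):
        return volume_at_dose(curve, dose_pct_rx=float(m.group(1)), plan=plan)
    raise ValueError(f"unrecognized dose metric {metric!r}")


#: Full per-structure index set computed by evaluate_dosimetry (superset of
#: the metrics of record; covers every constrained quantity).
STRUCTURE_METRICS: dict[str, tuple[str, ...]] = {
    "CTV": ("Dmean", "Dmax", "V100%", "D99%"),
    "Spinal Cord": ("Dmean", "Dmax"),
    "Kidney L": ("Dmean", "Dmax"),
    "Kidney R": ("Dmean", "Dmax"),
    "Bladder": ("Dmean", "Dmax", "D50%", "D0.03cc"),
    "Femoral Head L": ("Dmean", "Dmax", "D15%"),
    "Femoral Head R": ("Dmean", "Dmax", "D15%"),
    "Pelvic Bone": ("Dmean", "Dmax"),
    "Rectum": ("Dmean", "Dmax", "D50%", "D0.03cc"),
}


def structure_dvi(dose: VolumeGrid, mask: BinaryMask, structure: str,
                  plan: PlanConfig) -> DoseVolumeIndex:
    """All applicable dose–volume indices for one structure."""
    d_mean, d_max = mean_max_dose(dose, mask)
    extras = {}
    for metric in STRUCTURE_METRICS.get(structure, ()):
        if metric not in ("Dmean", "Dmax"):
            extras[metric] = metric_value(metric, dose, mask, plan)
    return DoseVolumeIndex(structure, d_mean, d_max, extras)


def evaluate_dosimetry(dose: VolumeGrid, manual: StructureSet, auto: StructureSet,
                       plan: PlanConfig) -> pd.DataFrame:
    """Paired manual/auto dose–volume indices on one fixed dose distribution.

    Returns a long table with one row per (structure, provenance, metric),
    including a pass flag for each plan constraint on that metric. Structures
    missing from either set, or empty, are flagged in ``status`` rather than
    raising.
    """
    cons_by_key = {}
    for c in plan.constraints:
        cons_by_key.setdefault((c.structure, c.metric), []).append(c)

    rows = []
    names = [n for n in STRUCTURE_METRICS if n in manual or n in auto]
    for name in names:
        for prov, sset in (("manual", manual), ("auto", auto)):
            if name not in sset:
                rows.append(dict(structure=name, provenance=prov, metric=None,
                                 value=np.nan, constraint=None, constraint_pass=None,
                                 status="missing"))
                continue
            mask = sset[name]
            if mask.is_empty():
                rows.append(dict(structure=name, provenance=prov, metric=None,
                                 value=np.nan, constraint=None, constraint_pass=None,
                                 status="empty"))
                continue
            dvi = structure_dvi(dose, mask, name, plan)
            for metric in STRUCTURE_METRICS[name]:
                value = dvi.value(metric)
                cons = cons_by_key.get((name, metric), [])
                if cons:
                    for c in cons:
                        rows.append(dict(
                            structure=name, provenance=prov, metric=metric,
                            value=value, constraint=c.label(),
                            constraint_pass=bool(c.check(value, plan.prescription_cGy)),
                            status="ok",
                        ))
                else:
                    rows.append(dict(structure=name, provenance=prov, metric=metric,
                                     value=value, constraint=None,
                                     constraint_pass=None, status="ok"))
    return pd.DataFrame(rows)
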