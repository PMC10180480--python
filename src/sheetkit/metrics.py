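"""Geometry metrics on coarse-grained DNA configurations.

Implements the junction and pore observables used to assess nanosheet
planarity: arm axes by total-least-squares on base-pair midpoints, the
dimensionless junction planarity d_p (distance from a junction to the
plane touching the tips of the three unit arm vectors; 0 for coplanar
arms, sin(tilt) for a uniform out-of-plane tilt), inter-arm angles,
pore-quadrilateral diagonals and internal angles, corner-plane normal
angles, equilibration statistics on metric time series, and 1-D AFM
height-profile measures (pore spacing and discrete duplex-layer counts).

All outputs are rotation- and translation-invariant; angles in degrees,
lengths in nm.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .constants import NM_PER_SU
from .oxdna import BasePairMap, Snapshot

__all__ = [
    "JunctionSpec",
    "PoreSpec",
    "MetricSeries",
    "HeightProfile",
    "arm_axis",
    "junction_position",
    "planarity_dp",
    "junction_planarity",
    "inter_arm_angles",
    "equilibrium_stats",
    "pore_quadrilateral",
    "pore_internal_angles",
    "corner_plane_planarity",
    "analyze_height_profile",
    "layer_count",
]


@dataclass
class JunctionSpec:
    """Index map defining one junction: per-arm ordered nucleotide index
    lists (proximal -> distal, one strand side of each duplex; base-pair
    midpoints are resolved through a BasePairMap).  Junctions of a free
    F-unit have three arms (two arms plus the proximal core segment);
    corners of a pore quadrilateral may carry two."""

    junction_id: str
    arms: List[List[int]]
    arm_labels: Optional[List[str]] = None
    cholesterol_proximal: Optional[List[bool]] = None

    def __post_init__(self):
        flat = [i for arm in self.arms for i in arm]
        if len(set(flat)) != len(flat):
            raise ValueError(f"junction {self.junction_id}: arms must be disjoint")
        if any(len(arm) < 2 for arm in self.arms):
            raise ValueError(
                f"junction {self.junction_id}: each arm needs >= 2 base pairs"
            )
        if len(self.arms) not in (2, 3):
            raise ValueError(
                f"junction {self.junction_id}: expected 2 or 3 arms, got {len(self.arms)}"
            )


@dataclass
class PoreSpec:
    """Four corner junctions X, Y, Z, W in cyclic order, with the two
    pore-internal arms of each corner named by index into its arm list."""

    corners: Dict[str, JunctionSpec]
    internal_arms: Dict[str, Tuple[int, int]]

    CYCLIC = ("X", "Y", "Z", "W")

    def __post_init__(self):
        if tuple(self.corners) != self.CYCLIC:
            raise ValueError("corners must be labelled X, Y, Z, W in cyclic order")
        for label, (i, j) in self.internal_arms.items():
            n = len(self.corners[label].arms)
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(
                    f"corner {label}: internal arm designation ({i}, {j}) does not "
                    f"reference two distinct arms of {n}"
                )


@dataclass
class MetricSeries:
    """Per-frame values of one metric with optional equilibrium summary."""

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""
    equilibrium_mean: Optional[float] = None
    equilibrium_sd: Optional[float] = None
    equilibrium_window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")
        if not np.isfinite(self.values).all():
            raise ValueError(f"metric {self.name}: non-finite values")


@dataclass
class HeightProfile:
    """1-D AFM scan line: positions (nm, uniform spacing) and heights (nm)."""

    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.positions) != len(self.heights):
            raise ValueError("positions and heights must have equal length")
        if len(self.positions) >= 2:
            d = np.diff(self.positions)
            if (d <= 0).any():
                raise ValueError("positions must be increasing")
            if np.abs(d - d[0]).max() > 1e-6:
                raise ValueError("non-uniform sampling (pixel spacing varies)")

    @property
    def pixel_size(self) -> float:
        if len(self.positions) < 2:
            raise ValueError("profile too short to define a pixel size")
        return float(self.positions[1] - self.positions[0])


# ---------------------------------------------------------------------------
# base-pair midpoints and arm axes


def _bp_midpoints(snapshot: Snapshot, pairing: BasePairMap, indices: Sequence[int]) -> np.ndarray:
    partner = pairing.partner()
    mids = []
    for i in indices:
        if i not in partner:
            raise ValueError(f"nucleotide {i} has no base-pair partner in the map")
        mids.append(0.5 * (snapshot.positions[i] + snapshot.positions[partner[i]]))
    return np.array(mids)


def arm_axis(
    snapshot: Snapshot, pairing: BasePairMap, arm: Sequence[int]
) -> Tuple[np.ndarray, np.ndarray]:
    """(direction, origin) of a duplex arm.

    Direction is the principal axis (total-least-squares line) of the
    base-pair midpoints, sign-fixed to point proximal -> distal along the
    given index order; origin is the midpoint centroid.
    """
    if len(arm) < 2:
        raise ValueError("an arm needs at least 2 base pairs")
    mids = _bp_midpoints(snapshot, pairing, arm)
    centroid = mids.mean(axis=0)
    centered = mids - centroid
    if np.linalg.norm(centered) < 1e-12:
        raise ValueError("degenerate arm: all base-pair midpoints coincide")
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, mids[-1] - mids[0]) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction), centroid


def junction_position(
    snapshot: Snapshot, pairing: BasePairMap, junction: JunctionSpec
) -> np.ndarray:
    """Centroid of the proximal base-pair midpoints of the junction's arms."""
    prox = [arm[0] for arm in junction.arms]
    return _bp_midpoints(snapshot, pairing, prox).mean(axis=0)


# ---------------------------------------------------------------------------
# planarity and angles


def _require_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-3:
        raise ValueError(f"{name} is not a unit vector (norm {n:.6f})")
    return v / n


def planarity_dp(
    junction_point: np.ndarray, e1: np.ndarray, e2: np.ndarray, e3: np.ndarray
) -> float:
    """Distance from the junction to the plane through the tips of the
    three unit arm vectors anchored at it; dimensionless, 0 iff the arms
    are coplanar."""
    j = np.asarray(junction_point, dtype=float)
    tips = np.array([j + _require_unit(e, f"e{k+1}") for k, e in enumerate((e1, e2, e3))])
    n = np.cross(tips[1] - tips[0], tips[2] - tips[0])
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("degenerate plane: arm-vector tips are collinear")
    return float(abs(np.dot(n / nn, j - tips[0])))


def junction_planarity(
    snapshot: Snapshot, pairing: BasePairMap, junction: JunctionSpec
) -> float:
    """d_p of a three-arm junction computed from a configuration."""
    if len(junction.arms) != 3:
        raise ValueError("junction planarity requires exactly three arms")
    j = junction_position(snapshot, pairing, junction)
    axes = [arm_axis(snapshot, pairing, arm)[0] for arm in junction.arms]
    return planarity_dp(j, *axes)


def inter_arm_angles(arm_axes: Mapping[str, np.ndarray]) -> Dict[str, float]:
    """Angles (degrees) between consecutive pairs of arm vectors.

    Accepts the junction-1 triple (e1..e3), the junction-2 triple
    (e4..e6), or all six; returns α_ij for j > i within each junction,
    e.g. {"a12": ..., "a13": ..., "a23": ...}.
    """
    keys = sorted(arm_axes)
    vecs = {k: _require_unit(arm_axes[k], k) for k in keys}
    groups = [
        [k for k in keys if k in ("e1", "e2", "e3")],
        [k for k in keys if k in ("e4", "e5", "e6")],
    ]
    out: Dict[str, float] = {}
    for group in groups:
        for a_i in range(len(group)):
            for a_j in range(a_i + 1, len(group)):
                ki, kj = group[a_i], group[a_j]
                cosang = np.clip(np.dot(vecs[ki], vecs[kj]), -1.0, 1.0)
                out[f"a{ki[1]}{kj[1]}"] = float(np.rad2deg(np.arccos(cosang)))
    if not out:
        raise ValueError("arm_axes must use keys e1..e6")
    return out


def equilibrium_stats(
    series: MetricSeries, last_fraction: float = 0.5
) -> Tuple[float, float, Tuple[float, float]]:
    """Mean and SD over the trailing window of a metric series; the
    window is recorded on the series and returned."""
    if not 0 < last_fraction <= 1:
        raise ValueError("last_fraction must lie in (0, 1]")
    n = len(series.values)
    k = max(int(np.ceil(n * last_fraction)), 1)
    if k < 4:
        raise ValueError(f"equilibrium window holds {k} frames; need at least 4")
    window_vals = series.values[n - k :]
    window = (float(series.times[n - k]), float(series.times[-1]))
    mean = float(window_vals.mean())
    sd = float(window_vals.std(ddof=1))
    series.equilibrium_mean, series.equilibrium_sd = mean, sd
    series.equilibrium_window = window
    return mean, sd, window


# ---------------------------------------------------------------------------
# pore quadrilateral


def _corner_positions(
    snapshot: Snapshot, pairing: BasePairMap, pore: PoreSpec
) -> Dict[str, np.ndarray]:
    out = {}
    for label, spec in pore.corners.items():
        try:
            out[label] = junction_position(snapshot, pairing, spec)
        except ValueError as exc:
            raise ValueError(f"pore corner {label} unresolvable: {exc}") from exc
    return out


def pore_quadrilateral(
    snapshot: Snapshot, pairing: BasePairMap, pore: PoreSpec
) -> Tuple[float, float, Dict[str, np.ndarray]]:
    """(diag_XZ_nm, diag_YW_nm, corner positions).  Snapshot positions are
    simulation units; diagonals are returned in nm."""
    c = _corner_positions(snapshot, pairing, pore)
    diag_xz = float(np.linalg.norm(c["X"] - c["Z"])) * NM_PER_SU
    diag_yw = float(np.linalg.norm(c["Y"] - c["W"])) * NM_PER_SU
    return diag_xz, diag_yw, c


def pore_internal_angles(
    snapshot: Snapshot, pairing: BasePairMap, pore: PoreSpec
) -> Dict[str, float]:
    """Angle (degrees) at each corner between its two pore-internal arm
    axes, keyed alpha/beta/gamma/delta for X/Y/Z/W."""
    greek = dict(zip(PoreSpec.CYCLIC, ("alpha", "beta", "gamma", "delta")))
    out = {}
    for label, spec in pore.corners.items():
        if label not in pore.internal_arms:
            raise ValueError(f"corner {label} has no internal-arm designation")
        i, j = pore.internal_arms[label]
        ei, _ = arm_axis(snapshot, pairing, spec.arms[i])
        ej, _ = arm_axis(snapshot, pairing, spec.arms[j])
        cosang = np.clip(np.dot(ei, ej), -1.0, 1.0)
        out[greek[label]] = float(np.rad2deg(np.arccos(cosang)))
    return out


def corner_plane_planarity(corner_positions) -> Dict[str, float]:
    """Pairwise angles (degrees, unsigned, 0-90) between the normals of
    the four corner planes of a quadrilateral.

    The plane of corner X passes through its two cyclic neighbors and
    itself (W, X, Y), and so on around the cycle.  A perfectly planar
    quadrilateral yields all six angles equal to 0.
    """
    if isinstance(corner_positions, dict):
        pts = [np.asarray(corner_positions[k], dtype=float) for k in PoreSpec.CYCLIC]
    else:
        pts = [np.asarray(p, dtype=float) for p in corner_positions]
    if len(pts) != 4:
        raise ValueError("need exactly four corner positions in cyclic order")
    labels = PoreSpec.CYCLIC
    normals = {}
    for k in range(4):
        prev_pt, this_pt, next_pt = pts[(k - 1) % 4], pts[k], pts[(k + 1) % 4]
        n = np.cross(prev_pt - this_pt, next_pt - this_pt)
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            raise ValueError(
                f"collinear corner triple around {labels[k]}: no corner plane"
            )
        normals[labels[k]] = n / nn
    out = {}
    for a in range(4):
        for b in range(a + 1, 4):
            la, lb = labels[a], labels[b]
            c = min(abs(float(np.dot(normals[la], normals[lb]))), 1.0)
            out[f"{la}{lb}"] = float(np.rad2deg(np.arccos(c)))
    return out


# ---------------------------------------------------------------------------
# AFM height profiles


def layer_count(height_nm: float, layer_height_nm: float = 2.0) -> int:
    """Discrete duplex-layer count of a plateau: round(h / layer height),
    floored at zero."""
    return max(int(round(height_nm / layer_height_nm)), 0)


@dataclass
class HeightProfileAnalysis:
    pore_positions_nm: np.ndarray
    mean_spacing_nm: Optional[float]
    spacing_sd_nm: Optional[float]
    segment_heights_nm: List[float]
    layer_counts: List[int]


def analyze_height_profile(
    profile: HeightProfile,
    layer_height_nm: float = 2.0,
    prominence_nm: Optional[float] = None,
) -> HeightProfileAnalysis:
    """Locate pores and quantize plateau thickness on a 1-D height trace.

    Pores appear as dips; they are found as local maxima of the pore
    depth signal max(h) − h with a prominence threshold (default half a
    duplex layer).  Spacing is the mean gap between consecutive pore
    centers.  Segments between pores (and the profile ends) are assigned
    discrete layer counts from their median height.
    """
    if len(profile.heights) < 3:
        raise ValueError("need at least 3 samples to analyze a profile")
    if profile.pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    if prominence_nm is None:
        prominence_nm = 0.5 * layer_height_nm
    depth = profile.heights.max() - profile.heights
    idx, _props = find_peaks(depth, prominence=prominence_nm)
    pore_pos = profile.positions[idx]

    if len(pore_pos) >= 2:
        gaps = np.diff(pore_pos)
        mean_spacing = float(gaps.mean())
        spacing_sd = float(gaps.std(ddof=1)) if len(gaps) > 1 else 0.0
    else:
        mean_spacing = spacing_sd = None

    bounds = np.concatenate([[0], idx, [len(profile.heights)]])
    seg_heights: List[float] = []
    counts: List[int] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = profile.heights[a:b]
        if len(seg) == 0:
            continue
        # median of the central half avoids dip shoulders
        lo, hi = len(seg) // 4, max(len(seg) - len(seg) // 4, len(seg) // 4 + 1)
        h = float(np.median(seg[lo:hi]))
        seg_heights.append(h)
        counts.append(layer_count(h, layer_height_nm))
    return HeightProfileAnalysis(
        pore_positions_nm=pore_pos,
        mean_spacing_nm=mean_spacing,
        spacing_sd_nm=spacing_sd,
        segment_heights_nm=seg_heights,
        layer_counts=counts,
    )
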