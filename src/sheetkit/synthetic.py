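"""Seeded generators for every input the analysis pipeline consumes.

These are statistical emulations for exercising the analysis code, not
physical simulations: no forces, no thermostat.  Each generator is a
pure function of its parameters and seed (identical inputs give
byte-identical artifacts) and exports a ground-truth record of the
injected parameters so recovery tests can close the loop.

Generated artifacts:

* near-planar F-unit and nanopore nucleotide configurations in oxDNA
  format, with controllable uniform out-of-plane tilt and positional
  noise (a uniform tilt of the three junction duplexes makes the
  junction planarity metric exactly sin(tilt));
* exponential-relaxation pseudo-trajectories of the F-unit tilt;
* periodic AFM-like 1-D height profiles with quantized layer heights and
  pore dips;
* staged interfacial rheology time sweeps with sigmoidal plateau
  transitions.

Nucleotide beads sit at the base interaction site, offset ±0.5 nm from
the duplex center-line perpendicular to the axis, with ``a1`` pointing
at the pairing partner; sticky-end stubs are rendered single-stranded
(unpaired) so geometric pairing has negatives.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .constants import NM_PER_SU
from .design import FUnitDesign
from .mechanics import RheologySweep
from .metrics import HeightProfile, JunctionSpec, PoreSpec
from .oxdna import (
    BasePairMap,
    Snapshot,
    Topology,
    Trajectory,
    write_configuration,
    write_topology,
)

__all__ = [
    "DistortionParams",
    "RelaxationParams",
    "GroundTruth",
    "generate_funit_snapshot",
    "generate_pore_snapshot",
    "generate_relaxation_trajectory",
    "generate_height_profile",
    "generate_rheology_sweep",
    "RheologyPhase",
    "FUnitArtifact",
    "PoreArtifact",
    "TrajectoryArtifact",
]

#: half-separation of paired beads across the duplex axis, nm
_BEAD_OFFSET_NM = 0.5

#: default equilibrium tilt giving an equilibrium planarity d_p of 0.2
DEFAULT_EQUILIBRIUM_TILT_DEG = math.degrees(math.asin(0.2))


@dataclass
class DistortionParams:
    """Controlled distortion of generated configurations."""

    uniform_tilt_deg: float = 0.0
    positional_noise_nm: float = 0.0
    #: in-plane arm azimuths (deg from the core direction) for e1 and e2;
    #: junction 2 mirrors them
    junction_angle_overrides: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        if self.positional_noise_nm < 0:
            raise ValueError("positional noise must be non-negative")
        if not 0 <= self.uniform_tilt_deg < 90:
            raise ValueError("uniform tilt must lie in [0, 90) deg")


@dataclass
class RelaxationParams:
    """Exponential approach of the junction tilt to equilibrium."""

    n_frames: int = 200
    frame_dt_taub: float = 1.0
    initial_tilt_deg: float = 60.0
    equilibrium_tilt_deg: float = DEFAULT_EQUILIBRIUM_TILT_DEG
    relaxation_time_taub: float = 10.0
    noise_deg: float = 1.0
    positional_noise_nm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames")
        if self.relaxation_time_taub <= 0:
            raise ValueError("relaxation time must be positive")


@dataclass
class GroundTruth:
    """Injected parameters of one generated artifact, JSON-serializable."""

    kind: str
    seed: int
    data: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(
            {"kind": self.kind, "seed": self.seed, **self.data},
            indent=2,
            default=default,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


# ---------------------------------------------------------------------------
# F-unit construction


def _perp(axis: np.ndarray) -> np.ndarray:
    p = np.cross(axis, np.array([0.0, 0.0, 1.0]))
    n = np.linalg.norm(p)
    if n < 1e-9:  # vertical axis
        p = np.cross(axis, np.array([1.0, 0.0, 0.0]))
        n = np.linalg.norm(p)
    return p / n


class _BeadBuilder:
    """Accumulates per-nucleotide positions/versors for a topology whose
    strand layout is fixed up front."""

    def __init__(self, n: int):
        self.pos = np.full((n, 3), np.nan)
        self.a1 = np.full((n, 3), np.nan)
        self.a3 = np.full((n, 3), np.nan)

    def duplex(self, mids_nm: np.ndarray, axis: np.ndarray, side_a: Sequence[int], side_b: Sequence[int]):
        """Place the two strands of a duplex element: bp k midpoint
        ``mids_nm[k]``, bead side_a[k] at +offset, side_b[k] at -offset."""
        p = _perp(axis)
        for k, m in enumerate(mids_nm):
            ia, ib = side_a[k], side_b[k]
            self.pos[ia] = m + _BEAD_OFFSET_NM * p
            self.pos[ib] = m - _BEAD_OFFSET_NM * p
            self.a1[ia] = -p
            self.a1[ib] = p
            self.a3[ia] = axis
            self.a3[ib] = -axis

    def single(self, mids_nm: np.ndarray, axis: np.ndarray, indices: Sequence[int]):
        p = _perp(axis)
        for k, m in enumerate(mids_nm):
            self.pos[indices[k]] = m
            self.a1[indices[k]] = p
            self.a3[indices[k]] = axis

    def snapshot(self, time: float = 0.0, box_nm: float = 100.0) -> Snapshot:
        if np.isnan(self.pos).any():
            raise RuntimeError("not all beads were placed")
        return Snapshot(
            time=time,
            box=np.full(3, box_nm / NM_PER_SU),
            positions=self.pos / NM_PER_SU,
            a1=self.a1.copy(),
            a3=self.a3.copy(),
        )


def _funit_topology(design: FUnitDesign, seqs) -> Topology:
    la, lc = design.strand_a_len, design.arm_bp
    bases = list(seqs.a()) + list(seqs.b()) + list(seqs.c()) * 4
    strand_ids, n3, n5 = [], [], []
    off = 0
    for sid, ln in enumerate([la, la, lc, lc, lc, lc], start=1):
        for k in range(ln):
            strand_ids.append(sid)
            n5.append(off + k - 1 if k > 0 else -1)
            n3.append(off + k + 1 if k < ln - 1 else -1)
        off += ln
    return Topology(
        strand_ids=np.array(strand_ids),
        bases=np.array(bases, dtype="U1"),
        neighbor_3prime=np.array(n3),
        neighbor_5prime=np.array(n5),
    )


def _funit_index_maps(design: FUnitDesign) -> dict:
    """Nucleotide index lists (bp ordered proximal -> distal) for every
    duplex element and sticky-end stub of the canonical F-unit layout
    [A, B, C1, C2, C3, C4]."""
    se, arm, core = design.se_bp, design.arm_bp, design.core_bp
    la = design.strand_a_len
    off_a, off_b = 0, la
    off_c = [2 * la + k * arm for k in range(4)]
    s_arm1, s_core, s_arm2, s_tail = se, se + arm, se + arm + core, se + arm + core + arm
    return {
        # core bp k: proximal at junction 1
        "core": {
            "a": [off_a + s_core + k for k in range(core)],
            "b": [off_b + s_core + (core - 1 - k) for k in range(core)],
        },
        # four arm duplexes; "a"-side is the A/B strand, "c"-side the C strand
        "arm_e1": {
            "a": [off_a + s_arm1 + (arm - 1 - k) for k in range(arm)],
            "c": [off_c[0] + k for k in range(arm)],
        },
        "arm_e4": {
            "a": [off_a + s_arm2 + k for k in range(arm)],
            "c": [off_c[1] + (arm - 1 - k) for k in range(arm)],
        },
        "arm_e5": {
            "a": [off_b + s_arm1 + (arm - 1 - k) for k in range(arm)],
            "c": [off_c[2] + k for k in range(arm)],
        },
        "arm_e2": {
            "a": [off_b + s_arm2 + k for k in range(arm)],
            "c": [off_c[3] + (arm - 1 - k) for k in range(arm)],
        },
        # sticky-end stubs ordered from the arm tip outward
        "se_e1": [off_a + (se - 1 - j) for j in range(se)],
        "se_e4": [off_a + s_tail + j for j in range(se)],
        "se_e5": [off_b + (se - 1 - j) for j in range(se)],
        "se_e2": [off_b + s_tail + j for j in range(se)],
    }


def _funit_beads(
    design: FUnitDesign,
    tilt_deg: float,
    azimuths: Tuple[float, float],
) -> Tuple[_BeadBuilder, dict, dict]:
    """Geometric realization of the F-unit at a uniform out-of-plane tilt.

    The core is rendered as a shallow tent so that at *both* junctions
    every one of the three incident duplex directions has out-of-plane
    inclination exactly ``tilt_deg``, making d_p = sin(tilt) exact.
    """
    rise = design.rise_nm
    phi = math.radians(tilt_deg)
    core_len = design.core_bp * rise
    idx = _funit_index_maps(design)
    n = 2 * design.strand_a_len + 4 * design.arm_bp
    bb = _BeadBuilder(n)

    j1 = np.zeros(3)
    j2 = np.array([core_len, 0.0, 0.0])
    # tent-shaped core: apex over the center, slope tan(phi) from each end
    s = (np.arange(design.core_bp) + 0.5) / design.core_bp
    core_mids = np.stack(
        [s * core_len, np.zeros_like(s), core_len * math.tan(phi) * np.minimum(s, 1 - s)],
        axis=1,
    )
    bb.duplex(core_mids, np.array([math.cos(phi), 0.0, math.sin(phi)]), idx["core"]["a"], idx["core"]["b"])

    def arm_dir(azimuth_deg: float, mirror: bool) -> np.ndarray:
        az = math.radians(azimuth_deg)
        d = np.array(
            [math.cos(phi) * math.cos(az), math.cos(phi) * math.sin(az), math.sin(phi)]
        )
        if mirror:  # junction 2: rotate 180 deg about z
            d = np.array([-d[0], -d[1], d[2]])
        return d

    dirs = {
        "e1": arm_dir(azimuths[0], False),
        "e2": arm_dir(azimuths[1], False),
        "e4": arm_dir(azimuths[0], True),
        "e5": arm_dir(azimuths[1], True),
    }
    origins = {"e1": j1, "e2": j1, "e4": j2, "e5": j2}
    for name in ("e1", "e2", "e4", "e5"):
        d, o = dirs[name], origins[name]
        k = np.arange(design.arm_bp) + 1.0
        arm_mids = o[None, :] + (k * rise)[:, None] * d[None, :]
        el = idx[f"arm_{name}"]
        bb.duplex(arm_mids, d, el["a"], el["c"])
        ks = np.arange(design.se_bp) + design.arm_bp + 1.0
        bb.single(o[None, :] + (ks * rise)[:, None] * d[None, :], d, idx[f"se_{name}"])
    return bb, idx, {"junctions": (j1, j2), "directions": dirs}


def _funit_junction_specs(design: FUnitDesign, idx: dict) -> Tuple[JunctionSpec, JunctionSpec]:
    half = min(10, design.core_bp // 2)
    core_a = idx["core"]["a"]
    j1 = JunctionSpec(
        junction_id="1",
        arms=[idx["arm_e1"]["a"], idx["arm_e2"]["a"], core_a[:half]],
        arm_labels=["e1", "e2", "e3"],
        cholesterol_proximal=[False, True, False],
    )
    j2 = JunctionSpec(
        junction_id="2",
        arms=[idx["arm_e4"]["a"], idx["arm_e5"]["a"], core_a[::-1][:half]],
        arm_labels=["e4", "e5", "e6"],
        cholesterol_proximal=[False, True, False],
    )
    return j1, j2


def _funit_pairing(design: FUnitDesign, idx: dict) -> BasePairMap:
    pairs = list(zip(idx["core"]["a"], idx["core"]["b"]))
    for name in ("arm_e1", "arm_e2", "arm_e4", "arm_e5"):
        pairs += list(zip(idx[name]["a"], idx[name]["c"]))
    return BasePairMap.from_pairs(pairs, provenance="design")


@dataclass
class FUnitArtifact:
    topology: Topology
    snapshot: Snapshot
    junctions: Tuple[JunctionSpec, JunctionSpec]
    pairing: BasePairMap
    ground_truth: GroundTruth

    def write(self, basepath) -> Dict[str, Path]:
        base = Path(basepath)
        paths = {
            "topology": base.with_suffix(".top"),
            "configuration": base.with_suffix(".dat"),
            "ground_truth": base.with_suffix(".json"),
        }
        write_topology(self.topology, paths["topology"])
        write_configuration(self.topology, [self.snapshot], paths["configuration"])
        self.ground_truth.write(paths["ground_truth"])
        return paths


def generate_funit_snapshot(
    design: Optional[FUnitDesign] = None,
    distortion: DistortionParams = DistortionParams(),
) -> FUnitArtifact:
    """One F-unit configuration with ground truth.

    At zero tilt and zero noise the configuration is exactly planar; a
    uniform tilt φ gives junction planarity d_p = sin φ at both
    junctions.
    """
    design = design or FUnitDesign()
    if design.sequences is None:
        design = design.with_random_sequences(seed=distortion.seed)
    azimuths = distortion.junction_angle_overrides or (150.0, -120.0)
    rng = np.random.default_rng(distortion.seed)
    bb, idx, geom = _funit_beads(design, distortion.uniform_tilt_deg, azimuths)
    if distortion.positional_noise_nm > 0:
        bb.pos += rng.normal(0.0, distortion.positional_noise_nm, bb.pos.shape)
    topo = _funit_topology(design, design.sequences)
    snap = bb.snapshot()
    j1, j2 = _funit_junction_specs(design, idx)
    pairing = _funit_pairing(design, idx)
    gap = (azimuths[0] - azimuths[1]) % 360.0
    truth = GroundTruth(
        kind="funit_snapshot",
        seed=distortion.seed,
        data={
            "uniform_tilt_deg": distortion.uniform_tilt_deg,
            "positional_noise_nm": distortion.positional_noise_nm,
            "expected_dp": math.sin(math.radians(distortion.uniform_tilt_deg)),
            "arm_azimuths_deg": list(azimuths),
            "inplane_angles_deg": {
                "a12": min(gap, 360.0 - gap),
                "a13": abs(azimuths[0]),
                "a23": abs(azimuths[1]),
            },
            "junctions_nm": [geom["junctions"][0], geom["junctions"][1]],
            "arm_directions": {k: v for k, v in geom["directions"].items()},
            "base_pairs": sorted(map(list, pairing.pairs)),
            "strand_lengths": [design.strand_a_len] * 2 + [design.arm_bp] * 4,
            "junction_arms": {"1": j1.arms, "2": j2.arms},
        },
    )
    return FUnitArtifact(topo, snap, (j1, j2), pairing, truth)


# ---------------------------------------------------------------------------
# nanopore


@dataclass
class PoreArtifact:
    topology: Topology
    snapshot: Snapshot
    pore: PoreSpec
    pairing: BasePairMap
    ground_truth: GroundTruth

    def write(self, basepath) -> Dict[str, Path]:
        base = Path(basepath)
        paths = {
            "topology": base.with_suffix(".top"),
            "configuration": base.with_suffix(".dat"),
            "ground_truth": base.with_suffix(".json"),
        }
        write_topology(self.topology, paths["topology"])
        write_configuration(self.topology, [self.snapshot], paths["configuration"])
        self.ground_truth.write(paths["ground_truth"])
        return paths


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    ax, ay, az = a
    k = np.array([[0, -az, ay], [az, 0, -ax], [-ay, ax, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(a, a)


def generate_pore_snapshot(
    design: Optional[FUnitDesign] = None,
    junction_angle_deg: float = 80.0,
    distortion: DistortionParams = DistortionParams(),
    arm_bp_for_spec: int = 12,
) -> PoreArtifact:
    """A four-corner nanopore quadrilateral: corners X, Y, Z, W joined by
    straight duplex sides of 63 bp (X-Y, Z-W, containing a core) and
    42 bp (Y-Z, W-X) contour length.

    ``uniform_tilt_deg`` folds the quadrilateral about the X-Z diagonal
    (a known out-of-plane distortion for corner-plane recovery tests);
    positional noise is per-bead Gaussian.
    """
    design = design or FUnitDesign()
    if not 0 < junction_angle_deg < 180:
        raise ValueError("junction angle must lie in (0, 180) deg")
    rng = np.random.default_rng(distortion.seed)
    rise = design.rise_nm
    a = design.side_long_bp * rise
    b = design.side_short_bp * rise
    th = math.radians(junction_angle_deg)
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([math.cos(th), math.sin(th), 0.0])
    corners = {"X": np.zeros(3), "Y": a * u, "Z": a * u + b * v, "W": b * v}
    sides = [
        ("XY", "X", "Y", design.side_long_bp),
        ("YZ", "Y", "Z", design.side_short_bp),
        ("ZW", "Z", "W", design.side_long_bp),
        ("WX", "W", "X", design.side_short_bp),
    ]
    n_total = 2 * sum(nbp for *_x, nbp in sides)
    bb = _BeadBuilder(n_total)
    strand_ids, bases, n3, n5 = [], [], [], []
    sense_idx: Dict[str, List[int]] = {}
    pairs = []
    off = 0
    sid = 0
    base_alphabet = np.array(list("ACGT"))
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for name, p_lab, q_lab, nbp in sides:
        p, q = corners[p_lab], corners[q_lab]
        # terminal base-pair midpoints sit exactly on the corner junctions
        frac = np.linspace(0.0, 1.0, nbp)
        mids = p[None, :] + frac[:, None] * (q - p)[None, :]
        axis = (q - p) / np.linalg.norm(q - p)
        side_sense = list(range(off, off + nbp))
        side_anti = list(range(off + nbp, off + 2 * nbp))
        # anti strand is antiparallel: bp k pairs sense[k] with anti[nbp-1-k]
        bb.duplex(mids, axis, side_sense, [side_anti[nbp - 1 - k] for k in range(nbp)])
        seq = rng.choice(base_alphabet, nbp)
        bases.extend(seq.tolist())
        bases.extend([comp[x] for x in seq[::-1].tolist()])
        for s_nt, ln in ((side_sense, nbp), (side_anti, nbp)):
            sid += 1
            for k in range(ln):
                strand_ids.append(sid)
                n5.append(s_nt[k] - 1 if k > 0 else -1)
                n3.append(s_nt[k] + 1 if k < ln - 1 else -1)
        pairs += [(side_sense[k], side_anti[nbp - 1 - k]) for k in range(nbp)]
        sense_idx[name] = side_sense
        off += 2 * nbp

    if distortion.uniform_tilt_deg:
        # fold the W-containing half about the X-Z diagonal
        rot = _rotation_about_axis(
            corners["Z"] - corners["X"], math.radians(distortion.uniform_tilt_deg)
        )
        moved = sense_idx["ZW"] + sense_idx["WX"]
        moved += [i + design.side_long_bp for i in sense_idx["ZW"]]
        moved += [i + design.side_short_bp for i in sense_idx["WX"]]
        moved = sorted(set(moved))
        bb.pos[moved] = (rot @ bb.pos[moved].T).T
        bb.a1[moved] = (rot @ bb.a1[moved].T).T
        bb.a3[moved] = (rot @ bb.a3[moved].T).T
    if distortion.positional_noise_nm > 0:
        bb.pos += rng.normal(0.0, distortion.positional_noise_nm, bb.pos.shape)

    topo = Topology(
        strand_ids=np.array(strand_ids),
        bases=np.array(bases, dtype="U1"),
        neighbor_3prime=np.array(n3),
        neighbor_5prime=np.array(n5),
    )
    snap = bb.snapshot(box_nm=200.0)
    m = arm_bp_for_spec
    corner_specs = {
        "X": (sense_idx["XY"][:m], sense_idx["WX"][::-1][:m]),
        "Y": (sense_idx["XY"][::-1][:m], sense_idx["YZ"][:m]),
        "Z": (sense_idx["YZ"][::-1][:m], sense_idx["ZW"][:m]),
        "W": (sense_idx["ZW"][::-1][:m], sense_idx["WX"][:m]),
    }
    pore = PoreSpec(
        corners={
            lab: JunctionSpec(junction_id=lab, arms=[list(a1), list(a2)])
            for lab, (a1, a2) in corner_specs.items()
        },
        internal_arms={lab: (0, 1) for lab in PoreSpec.CYCLIC},
    )
    d_long = math.sqrt(a * a + b * b + 2 * a * b * math.cos(th))
    d_short = math.sqrt(a * a + b * b - 2 * a * b * math.cos(th))
    truth = GroundTruth(
        kind="pore_snapshot",
        seed=distortion.seed,
        data={
            "junction_angle_deg": junction_angle_deg,
            "fold_angle_deg": distortion.uniform_tilt_deg,
            "positional_noise_nm": distortion.positional_noise_nm,
            "corners_nm": {k: val for k, val in corners.items()},
            "planar_diag_XZ_nm": d_long,
            "planar_diag_YW_nm": d_short,
            "internal_angles_deg": {
                "alpha": junction_angle_deg,
                "beta": 180 - junction_angle_deg,
                "gamma": junction_angle_deg,
                "delta": 180 - junction_angle_deg,
            },
            "corner_arms": {lab: [list(a1), list(a2)] for lab, (a1, a2) in corner_specs.items()},
            "internal_arms": {lab: [0, 1] for lab in PoreSpec.CYCLIC},
            "base_pairs": sorted(map(list, BasePairMap.from_pairs(pairs).pairs)),
        },
    )
    return PoreArtifact(topo, snap, pore, BasePairMap.from_pairs(pairs), truth)


# ---------------------------------------------------------------------------
# relaxation pseudo-trajectory


@dataclass
class TrajectoryArtifact:
    topology: Topology
    trajectory: Trajectory
    junctions: Tuple[JunctionSpec, JunctionSpec]
    pairing: BasePairMap
    ground_truth: GroundTruth

    def write(self, basepath) -> Dict[str, Path]:
        base = Path(basepath)
        paths = {
            "topology": base.with_suffix(".top"),
            "trajectory": base.with_suffix(".dat"),
            "ground_truth": base.with_suffix(".json"),
        }
        write_topology(self.topology, paths["topology"])
        write_configuration(self.topology, self.trajectory.snapshots, paths["trajectory"])
        self.ground_truth.write(paths["ground_truth"])
        return paths


def generate_relaxation_trajectory(
    design: Optional[FUnitDesign] = None,
    relax: RelaxationParams = RelaxationParams(),
) -> TrajectoryArtifact:
    """F-unit pseudo-trajectory whose tilt decays exponentially to an
    equilibrium value: frame k has tilt
    φ_k = φ_eq + (φ_0 − φ_eq)·exp(−t_k/τ) + ε_k with ε_k ~ N(0, noise)."""
    design = design or FUnitDesign()
    if design.sequences is None:
        design = design.with_random_sequences(seed=relax.seed)
    rng = np.random.default_rng(relax.seed)
    times = np.arange(relax.n_frames) * relax.frame_dt_taub
    decay = relax.equilibrium_tilt_deg + (
        relax.initial_tilt_deg - relax.equilibrium_tilt_deg
    ) * np.exp(-times / relax.relaxation_time_taub)
    eps = rng.normal(0.0, relax.noise_deg, relax.n_frames) if relax.noise_deg > 0 else np.zeros(relax.n_frames)
    tilts = np.clip(decay + eps, 0.0, 89.0)
    snapshots = []
    idx = None
    for k, (t, tilt) in enumerate(zip(times, tilts)):
        bb, idx, _geom = _funit_beads(design, float(tilt), (150.0, -120.0))
        if relax.positional_noise_nm > 0:
            bb.pos += rng.normal(0.0, relax.positional_noise_nm, bb.pos.shape)
        snap = bb.snapshot(time=float(t))
        snapshots.append(snap)
    topo = _funit_topology(design, design.sequences)
    traj = Trajectory(topo, snapshots)
    traj.validate()
    j1, j2 = _funit_junction_specs(design, idx)
    truth = GroundTruth(
        kind="relaxation_trajectory",
        seed=relax.seed,
        data={
            "n_frames": relax.n_frames,
            "frame_dt_taub": relax.frame_dt_taub,
            "initial_tilt_deg": relax.initial_tilt_deg,
            "equilibrium_tilt_deg": relax.equilibrium_tilt_deg,
            "equilibrium_dp": math.sin(math.radians(relax.equilibrium_tilt_deg)),
            "relaxation_time_taub": relax.relaxation_time_taub,
            "noise_deg": relax.noise_deg,
            "tilts_deg": tilts,
            "junction_arms": {"1": j1.arms, "2": j2.arms},
            "base_pairs": sorted(map(list, _funit_pairing(design, idx).pairs)),
        },
    )
    return TrajectoryArtifact(topo, traj, (j1, j2), _funit_pairing(design, idx), truth)


# ---------------------------------------------------------------------------
# AFM height profile


def generate_height_profile(
    spacing_nm: float = 25.0,
    n_pores: int = 8,
    layer_pattern: Sequence[int] = (1,),
    layer_height_nm: float = 2.0,
    noise_nm: float = 0.1,
    pixel_nm: float = 0.5,
    dip_width_nm: float = 2.0,
    seed: int = 0,
) -> Tuple[HeightProfile, GroundTruth]:
    """Periodic 1-D height trace: plateaus at integer duplex-layer heights
    separated by Gaussian pore dips every ``spacing_nm``."""
    if spacing_nm <= pixel_nm:
        raise ValueError("pore spacing must exceed the pixel size")
    if any(c < 0 for c in layer_pattern):
        raise ValueError("layer counts must be non-negative")
    rng = np.random.default_rng(seed)
    length = (n_pores + 1) * spacing_nm
    x = np.arange(0.0, length + pixel_nm / 2, pixel_nm)
    pore_centers = spacing_nm * (np.arange(n_pores) + 1.0)
    # plateau segments between pores (and the two ends), cycled pattern
    seg_of_x = np.searchsorted(pore_centers, x)
    counts = np.array([layer_pattern[s % len(layer_pattern)] for s in seg_of_x])
    heights = counts * layer_height_nm
    if n_pores:
        dip = np.zeros_like(x)
        for c in pore_centers:
            dip = np.maximum(dip, np.exp(-0.5 * ((x - c) / (dip_width_nm / 2.355)) ** 2))
        heights = heights * (1.0 - dip)
    if noise_nm > 0:
        heights = heights + rng.normal(0.0, noise_nm, len(x))
    profile = HeightProfile(positions=x, heights=heights)
    truth = GroundTruth(
        kind="height_profile",
        seed=seed,
        data={
            "spacing_nm": spacing_nm,
            "pore_positions_nm": pore_centers,
            "layer_pattern": list(layer_pattern),
            "layer_height_nm": layer_height_nm,
            "noise_nm": noise_nm,
            "pixel_nm": pixel_nm,
        },
    )
    return profile, truth


# ---------------------------------------------------------------------------
# rheology sweep


@dataclass
class RheologyPhase:
    """One protocol phase of a staged sweep."""

    duration_s: float
    storage_plateau: float  # G', N/m
    loss_plateau: float  # G'', N/m
    temperature_c: float = 25.0
    label: str = ""


#: staging that mimics a stepwise liquid/liquid assembly run: baseline
#: interface, AB addition, heating to 45 °C, and annealing back at 25 °C
DEFAULT_RHEOLOGY_PLAN = [
    RheologyPhase(3600.0, 1e-4, 5e-5, 25.0, "baseline"),
    RheologyPhase(3600.0, 1e-2, 2e-3, 25.0, "AB_500nM"),
    RheologyPhase(3600.0, 1e-1, 2e-2, 45.0, "heat_45C"),
    RheologyPhase(3600.0, 3e-1, 1.5e-2, 25.0, "anneal_25C"),
]


def generate_rheology_sweep(
    phases: Optional[Sequence[RheologyPhase]] = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    dt_s: float = 5.0,
    transition_s: float = 120.0,
) -> Tuple[RheologySweep, GroundTruth]:
    """Staged time sweep with sigmoidal plateau-to-plateau transitions and
    multiplicative noise of coefficient of variation ``noise_cv``."""
    phases = list(phases) if phases is not None else list(DEFAULT_RHEOLOGY_PLAN)
    if any(p.storage_plateau < 0 or p.loss_plateau < 0 for p in phases):
        raise ValueError("plateaus must be non-negative")
    rng = np.random.default_rng(seed)
    starts = np.concatenate([[0.0], np.cumsum([p.duration_s for p in phases])])
    t = np.arange(0.0, starts[-1], dt_s)
    gp = np.full_like(t, phases[0].storage_plateau)
    gpp = np.full_like(t, phases[0].loss_plateau)
    temp = np.full_like(t, phases[0].temperature_c)
    labels = np.array([phases[0].label] * len(t), dtype=object)
    for k in range(1, len(phases)):
        prev, cur = phases[k - 1], phases[k]
        # rise centered inside the new phase so the previous plateau's
        # trailing window is untouched
        center = starts[k] + transition_s / 2.0
        sig = expit((t - center) / (transition_s / 12.0))
        gp = gp + (cur.storage_plateau - prev.storage_plateau) * sig
        gpp = gpp + (cur.loss_plateau - prev.loss_plateau) * sig
        in_phase = t >= starts[k]
        temp[in_phase] = cur.temperature_c
        labels[in_phase] = cur.label
    if noise_cv > 0:
        gp = np.maximum(gp * (1.0 + rng.normal(0.0, noise_cv, len(t))), 0.0)
        gpp = np.maximum(gpp * (1.0 + rng.normal(0.0, noise_cv, len(t))), 0.0)
    sweep = RheologySweep(
        time_s=t,
        storage_modulus=gp,
        loss_modulus=gpp,
        temperature_c=temp,
        phase_labels=labels,
    )
    truth = GroundTruth(
        kind="rheology_sweep",
        seed=seed,
        data={
            "phase_boundaries_s": starts[1:-1],
            "storage_plateaus": [p.storage_plateau for p in phases],
            "loss_plateaus": [p.loss_plateau for p in phases],
            "temperatures_c": [p.temperature_c for p in phases],
            "labels": [p.label for p in phases],
            "noise_cv": noise_cv,
            "dt_s": dt_s,
            "transition_s": transition_s,
        },
    )
    return sweep, truth
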