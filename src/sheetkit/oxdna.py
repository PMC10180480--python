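"""Reading, writing, and validating oxDNA-style topology and configuration files.

The classic text dialect is used throughout: a topology file whose first
line is ``"<n_nucleotides> <n_strands>"`` followed by one
``"<strand_id> <base> <3'-neighbor> <5'-neighbor>"`` line per nucleotide
(``-1`` marks a chain terminus, indices are 0-based), and configuration
files made of frames with header lines ``t = ...``, ``b = ...``,
``E = ...`` followed by one row of 9 (or 15, with velocities) numbers per
nucleotide: position, the backbone-base versor ``a1``, the stacking
versor ``a3``, and optionally linear and angular velocity.

Positions in files are in oxDNA simulation units; :func:`to_nanometers`
converts to nm (0.8518 nm per unit).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import NM_PER_SU, WC_COMPLEMENT

__all__ = [
    "Topology",
    "Snapshot",
    "Trajectory",
    "BasePairMap",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_snapshot",
    "write_configuration",
    "to_nanometers",
    "from_nanometers",
    "derive_base_pairs",
]

_VERSOR_TOL = 1e-6


class OxdnaParseError(ValueError):
    """Malformed oxDNA file content."""


class OxdnaValidationError(ValueError):
    """Structurally inconsistent topology or configuration."""


@dataclass
class Topology:
    """Strand connectivity of an oxDNA system.

    ``strand_ids`` are 1-based (file convention); nucleotide indices are
    0-based.  ``neighbor_3prime[i]``/``neighbor_5prime[i]`` give the
    index of the 3'/5' neighbor of nucleotide ``i`` or ``-1``.
    """

    strand_ids: np.ndarray
    bases: np.ndarray
    neighbor_3prime: np.ndarray
    neighbor_5prime: np.ndarray

    @property
    def n_nucleotides(self) -> int:
        return len(self.strand_ids)

    @property
    def n_strands(self) -> int:
        return int(self.strand_ids.max()) if self.n_nucleotides else 0

    def strand_lengths(self) -> np.ndarray:
        """Number of nucleotides in each strand, ordered by strand id."""
        return np.bincount(self.strand_ids, minlength=self.n_strands + 1)[1:]

    def validate(self) -> None:
        n = self.n_nucleotides
        ids = np.unique(self.strand_ids)
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise OxdnaValidationError(
                "strand ids must form a contiguous 1..n_strands set"
            )
        for name, neigh in (("3'", self.neighbor_3prime), ("5'", self.neighbor_5prime)):
            bad = (neigh < -1) | (neigh >= n)
            if bad.any():
                raise OxdnaValidationError(
                    f"{name} neighbor index out of range at nucleotide "
                    f"{int(np.where(bad)[0][0])}"
                )
        if (self.neighbor_3prime == np.arange(n)).any() or (
            self.neighbor_5prime == np.arange(n)
        ).any():
            raise OxdnaValidationError("a nucleotide cannot be its own neighbor")
        for i in range(n):
            j = self.neighbor_3prime[i]
            if j >= 0 and self.neighbor_5prime[j] != i:
                raise OxdnaValidationError(
                    f"inconsistent neighbor chain: nucleotide {i}'s 3' neighbor "
                    f"{j} does not point back"
                )
            j = self.neighbor_5prime[i]
            if j >= 0 and self.neighbor_3prime[j] != i:
                raise OxdnaValidationError(
                    f"inconsistent neighbor chain: nucleotide {i}'s 5' neighbor "
                    f"{j} does not point back"
                )

    def __eq__(self, other) -> bool:  # structural equality
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            np.array_equal(self.strand_ids, other.strand_ids)
            and np.array_equal(self.bases, other.bases)
            and np.array_equal(self.neighbor_3prime, other.neighbor_3prime)
            and np.array_equal(self.neighbor_5prime, other.neighbor_5prime)
        )


@dataclass
class Snapshot:
    """One configuration frame.  Lengths in simulation units, time in τ_B."""

    time: float
    box: np.ndarray
    positions: np.ndarray
    a1: np.ndarray
    a3: np.ndarray
    energies: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocities: Optional[np.ndarray] = None
    angular_velocities: Optional[np.ndarray] = None

    @property
    def n_nucleotides(self) -> int:
        return len(self.positions)

    def validate(self, topology: Optional[Topology] = None) -> None:
        if topology is not None and topology.n_nucleotides != self.n_nucleotides:
            raise OxdnaValidationError(
                f"snapshot has {self.n_nucleotides} records but topology has "
                f"{topology.n_nucleotides} nucleotides"
            )
        for name, v in (("a1", self.a1), ("a3", self.a3)):
            norms = np.linalg.norm(v, axis=1)
            if np.abs(norms - 1.0).max() > _VERSOR_TOL:
                i = int(np.argmax(np.abs(norms - 1.0)))
                raise OxdnaValidationError(
                    f"{name} versor of nucleotide {i} is not unit length "
                    f"(norm {norms[i]:.8f})"
                )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; times strictly increasing."""

    topology: Topology
    snapshots: list

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def validate(self) -> None:
        t = self.times
        if len(t) > 1 and not (np.diff(t) > 0).all():
            k = int(np.where(np.diff(t) <= 0)[0][0])
            raise OxdnaValidationError(
                f"frame times not strictly increasing at frame {k + 1} "
                f"(t={t[k + 1]} after t={t[k]})"
            )
        for s in self.snapshots:
            s.validate(self.topology)


@dataclass(frozen=True)
class BasePairMap:
    """Unordered nucleotide index pairs flagged as base-paired."""

    pairs: frozenset
    provenance: str = "design"

    @classmethod
    def from_pairs(cls, pairs: Iterable, provenance: str = "design") -> "BasePairMap":
        norm = frozenset(tuple(sorted(map(int, p))) for p in pairs)
        seen: dict = {}
        for a, b in norm:
            for x in (a, b):
                if x in seen:
                    raise OxdnaValidationError(
                        f"nucleotide {x} appears in more than one base pair"
                    )
                seen[x] = True
        return cls(pairs=norm, provenance=provenance)

    def partner(self) -> dict:
        """Map nucleotide index -> paired partner index."""
        out: dict = {}
        for a, b in self.pairs:
            out[a] = b
            out[b] = a
        return out

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# file I/O


def read_topology(path) -> Topology:
    """Parse a classic oxDNA topology file."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise OxdnaParseError(f"{path}: empty topology file")
    head = lines[0].split()
    if len(head) != 2:
        raise OxdnaParseError(
            f"{path}:1: header must hold two integers (got {lines[0]!r})"
        )
    try:
        n, n_strands = int(head[0]), int(head[1])
    except ValueError:
        raise OxdnaParseError(f"{path}:1: non-integer header {lines[0]!r}") from None
    body = [ln for ln in lines[1:] if ln.strip()]
    if len(body) != n:
        raise OxdnaParseError(
            f"{path}: expected {n} nucleotide lines, found {len(body)}"
        )
    strand_ids = np.empty(n, dtype=int)
    bases = np.empty(n, dtype="U1")
    n3 = np.empty(n, dtype=int)
    n5 = np.empty(n, dtype=int)
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) != 4:
            raise OxdnaParseError(
                f"{path}:{i + 2}: expected 'strand base n3 n5', got {ln!r}"
            )
        try:
            strand_ids[i] = int(parts[0])
            n3[i] = int(parts[2])
            n5[i] = int(parts[3])
        except ValueError:
            raise OxdnaParseError(f"{path}:{i + 2}: malformed line {ln!r}") from None
        base = parts[1].upper()
        if base not in WC_COMPLEMENT:
            raise OxdnaParseError(f"{path}:{i + 2}: unknown base {parts[1]!r}")
        bases[i] = base
    topo = Topology(strand_ids, bases, n3, n5)
    if topo.n_strands != n_strands:
        raise OxdnaValidationError(
            f"{path}: header declares {n_strands} strands but body holds "
            f"{topo.n_strands}"
        )
    topo.validate()
    return topo


def write_topology(topology: Topology, path) -> None:
    topology.validate()
    out = [f"{topology.n_nucleotides} {topology.n_strands}"]
    for i in range(topology.n_nucleotides):
        out.append(
            f"{topology.strand_ids[i]} {topology.bases[i]} "
            f"{topology.neighbor_3prime[i]} {topology.neighbor_5prime[i]}"
        )
    Path(path).write_text("\n".join(out) + "\n")


def _fmt(values: Sequence[float]) -> str:
    return " ".join(f"{v:.12g}" for v in values)


def _parse_header_line(lines, k, key, path):
    if k >= len(lines) or not lines[k].lstrip().startswith(key):
        raise OxdnaParseError(
            f"{path}:{k + 1}: expected '{key} = ...' header line"
        )
    try:
        return np.array([float(x) for x in lines[k].split("=")[1].split()])
    except (IndexError, ValueError):
        raise OxdnaParseError(f"{path}:{k + 1}: malformed header {lines[k]!r}") from None


def read_trajectory(path, topology: Topology) -> Trajectory:
    """Parse a configuration/trajectory file against ``topology``."""
    lines = Path(path).read_text().splitlines()
    n = topology.n_nucleotides
    snapshots = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        frame_idx = len(snapshots)
        t = _parse_header_line(lines, k, "t", path)
        box = _parse_header_line(lines, k + 1, "b", path)
        energies = _parse_header_line(lines, k + 2, "E", path)
        k += 3
        rows = np.empty((n, 0))
        block = lines[k : k + n]
        if len(block) < n or any(ln.lstrip().startswith("t") for ln in block):
            raise OxdnaParseError(
                f"{path}: frame {frame_idx} holds fewer than {n} nucleotide rows"
            )
        try:
            rows = np.array([[float(x) for x in ln.split()] for ln in block])
        except ValueError:
            raise OxdnaParseError(
                f"{path}: frame {frame_idx}: non-numeric nucleotide row"
            ) from None
        if rows.shape[1] not in (9, 15):
            raise OxdnaParseError(
                f"{path}: frame {frame_idx}: rows must hold 9 or 15 numbers, "
                f"got {rows.shape[1]}"
            )
        snap = Snapshot(
            time=float(t[0]),
            box=box,
            energies=energies,
            positions=rows[:, 0:3],
            a1=rows[:, 3:6],
            a3=rows[:, 6:9],
            velocities=rows[:, 9:12] if rows.shape[1] == 15 else None,
            angular_velocities=rows[:, 12:15] if rows.shape[1] == 15 else None,
        )
        snap.validate(topology)
        snapshots.append(snap)
        k += n
    traj = Trajectory(topology, snapshots)
    traj.validate()
    return traj


def write_snapshot(topology: Topology, snapshot: Snapshot, path) -> None:
    """Write a single frame; absent velocities are written as zeros."""
    Path(path).write_text(_render_frame(topology, snapshot))


def write_configuration(topology: Topology, snapshots: Iterable[Snapshot], path) -> None:
    """Write a multi-frame trajectory file."""
    Path(path).write_text(
        "".join(_render_frame(topology, s) for s in snapshots)
    )


def _render_frame(topology: Topology, snapshot: Snapshot) -> str:
    snapshot.validate(topology)
    n = snapshot.n_nucleotides
    vel = snapshot.velocities if snapshot.velocities is not None else np.zeros((n, 3))
    ang = (
        snapshot.angular_velocities
        if snapshot.angular_velocities is not None
        else np.zeros((n, 3))
    )
    lines = [
        f"t = {snapshot.time:.12g}",
        f"b = {_fmt(snapshot.box)}",
        f"E = {_fmt(snapshot.energies)}",
    ]
    rows = np.hstack([snapshot.positions, snapshot.a1, snapshot.a3, vel, ang])
    lines.extend(_fmt(row) for row in rows)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# units


def to_nanometers(x):
    """Convert simulation-unit lengths (scalar or array) to nm."""
    return np.asarray(x, dtype=float) * NM_PER_SU if np.ndim(x) else float(x) * NM_PER_SU


def from_nanometers(x):
    """Inverse of :func:`to_nanometers`."""
    return np.asarray(x, dtype=float) / NM_PER_SU if np.ndim(x) else float(x) / NM_PER_SU


# ---------------------------------------------------------------------------
# base pairing


def derive_base_pairs(
    topology: Topology,
    snapshot: Optional[Snapshot] = None,
    mode: str = "design",
    design=None,
    max_distance_nm: float = 1.2,
    max_angle_deg: float = 30.0,
    max_displacement_angle_deg: float = 10.0,
) -> BasePairMap:
    """Derive the duplex base-pair map either from the design or geometrically.

    Design mode delegates to ``design.base_pair_map(topology)`` and returns
    the exact pairing implied by domain complementarity.  Geometric mode
    pairs Watson-Crick complementary nucleotides whose centers lie within
    ``max_distance_nm``, whose ``a1`` versors are anti-aligned within
    ``max_angle_deg``, and whose center-to-center displacement lies along
    the ``a1`` axis within ``max_displacement_angle_deg`` (this separates
    a true partner from the partner of an adjacent base pair, which sits
    almost as close but off-axis).  An ambiguous match raises an error
    listing the indices involved.
    """
    if mode == "design":
        if design is None:
            raise ValueError("design mode requires a FUnitDesign with domain maps")
        return design.base_pair_map(topology)
    if mode != "geometric":
        raise ValueError(f"unknown pairing mode {mode!r}")
    if snapshot is None:
        raise ValueError("geometric mode requires a snapshot")

    pos_nm = snapshot.positions * NM_PER_SU
    tree = cKDTree(pos_nm)
    cos_cut = np.cos(np.deg2rad(max_angle_deg))
    candidates: dict = {}
    for i, j in tree.query_pairs(r=max_distance_nm):
        if topology.bases[j] != WC_COMPLEMENT[topology.bases[i]]:
            continue
        # covalent neighbors along a strand are never a base pair
        if topology.neighbor_3prime[i] == j or topology.neighbor_5prime[i] == j:
            continue
        # anti-aligned backbone-base axes: a1_i . (-a1_j) close to 1
        if -float(np.dot(snapshot.a1[i], snapshot.a1[j])) < cos_cut:
            continue
        d = pos_nm[j] - pos_nm[i]
        dn = np.linalg.norm(d)
        if dn > 1e-12:
            cos_disp = np.cos(np.deg2rad(max_displacement_angle_deg))
            if float(np.dot(d / dn, snapshot.a1[i])) < cos_disp:
                continue
            if float(np.dot(-d / dn, snapshot.a1[j])) < cos_disp:
                continue
        candidates.setdefault(i, []).append(j)
        candidates.setdefault(j, []).append(i)
    ambiguous = {i: js for i, js in candidates.items() if len(js) > 1}
    if ambiguous:
        detail = "; ".join(
            f"nucleotide {i} matches {sorted(js)}" for i, js in sorted(ambiguous.items())
        )
        raise OxdnaValidationError(f"ambiguous geometric pairing: {detail}")
    pairs = {tuple(sorted((i, js[0]))) for i, js in candidates.items()}
    return BasePairMap.from_pairs(pairs, provenance="geometric")
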