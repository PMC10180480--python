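"""F-unit design model: segments, sequences, melting order, lattice geometry.

The F-unit is the minimal assembly unit of the nanosheet: three DNA
strands (A, B, C) forming one core duplex (21 bp by default), four arm
duplexes (16 bp) and four 10-nt sticky ends (SE1/SE1* and SE2/SE2*).
Strands A and B are partially complementary and form the core; every arm
is complementary to strand C; the unpaired strand ends are the sticky
ends that link F-units into a porous two-dimensional lattice.

Duplex lengths are chosen so hybridization is hierarchical on cooling:
the core melts highest, then the arms, then the sticky ends.  Melting
temperatures come from unified nearest-neighbor thermodynamics
(SantaLucia-type tables via Biopython) with an equivalent-monovalent
correction for divalent salt.

Lattice geometry is the idealized closed form: pore sides of
``arm + SE + core + arm`` = 63 bp and ``arm + SE + arm`` = 42 bp, a
parallelogram unit cell at the junction angle, and an open-area
(porosity) fraction from strip ownership of the duplex footprints.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .constants import DUPLEX_WIDTH_NM, RISE_NM_PER_BP, revcomp
from .oxdna import BasePairMap, Topology

__all__ = [
    "DesignSequences",
    "random_design_sequences",
    "FUnitDesign",
    "AnnealingProtocol",
    "MeltingConditions",
    "DomainTmSet",
    "LatticeGeometry",
    "IdealUnitModel",
    "validate_design",
    "domain_melting_temperatures",
    "duplex_tm",
    "assembly_order",
    "build_ideal_funit",
    "pore_lattice_geometry",
    "cholesterol_spacings",
    "lattice_porosity",
]


# ---------------------------------------------------------------------------
# sequences


@dataclass
class DesignSequences:
    """Domain sequences of the F-unit, written 5'->3' on the A/B strands.

    ``arm`` is the arm-duplex sequence as it reads on strands A and B, so
    strand C is its reverse complement.  Strand-level overrides allow
    validating externally supplied oligos against the domain model.
    """

    core: str
    arm: str
    se1: str
    se2: str
    strand_a: Optional[str] = None
    strand_b: Optional[str] = None
    strand_c: Optional[str] = None

    def expected_strand_a(self) -> str:
        return self.se1 + self.arm + self.core + self.arm + self.se2

    def expected_strand_b(self) -> str:
        return revcomp(self.se2) + self.arm + revcomp(self.core) + self.arm + revcomp(self.se1)

    def expected_strand_c(self) -> str:
        return revcomp(self.arm)

    def a(self) -> str:
        return self.strand_a or self.expected_strand_a()

    def b(self) -> str:
        return self.strand_b or self.expected_strand_b()

    def c(self) -> str:
        return self.strand_c or self.expected_strand_c()


def random_design_sequences(
    core_bp: int = 21,
    arm_bp: int = 16,
    se_bp: int = 10,
    seed: int = 0,
    gc_fraction: float = 0.5,
) -> DesignSequences:
    """GC-balanced random placeholder domains (the experimentally used
    oligo sequences are not bundled with this package)."""
    rng = np.random.default_rng(seed)

    def draw(n: int) -> str:
        n_gc = int(round(gc_fraction * n))
        pool = list(
            rng.choice(["G", "C"], n_gc).tolist()
            + rng.choice(["A", "T"], n - n_gc).tolist()
        )
        rng.shuffle(pool)
        return "".join(pool)

    return DesignSequences(core=draw(core_bp), arm=draw(arm_bp), se1=draw(se_bp), se2=draw(se_bp))


# ---------------------------------------------------------------------------
# design


@dataclass
class FUnitDesign:
    """Segment lengths, optional sequences, stoichiometry, cholesterol sites."""

    core_bp: int = 21
    arm_bp: int = 16
    se_bp: int = 10
    rise_nm: float = RISE_NM_PER_BP
    duplex_width_nm: float = DUPLEX_WIDTH_NM
    sequences: Optional[DesignSequences] = None
    stoichiometry: Tuple[float, float, float] = (1.0, 1.0, 10.0)
    #: (strand label, terminus) attachment markers; cholesterol sits on the
    #: 3' end of each arm strand C in the experimental construct
    cholesterol_sites: List[Tuple[str, str]] = field(
        default_factory=lambda: [(f"C{k}", "3'") for k in (1, 2, 3, 4)]
    )

    @property
    def side_long_bp(self) -> int:
        """Pore side containing a core: arm + SE + core + arm."""
        return 2 * self.arm_bp + self.se_bp + self.core_bp

    @property
    def side_short_bp(self) -> int:
        """Pore side without a core: arm + SE + arm."""
        return 2 * self.arm_bp + self.se_bp

    @property
    def strand_a_len(self) -> int:
        return self.core_bp + 2 * self.arm_bp + 2 * self.se_bp

    def with_random_sequences(self, seed: int = 0) -> "FUnitDesign":
        return FUnitDesign(
            core_bp=self.core_bp,
            arm_bp=self.arm_bp,
            se_bp=self.se_bp,
            rise_nm=self.rise_nm,
            duplex_width_nm=self.duplex_width_nm,
            sequences=random_design_sequences(self.core_bp, self.arm_bp, self.se_bp, seed),
            stoichiometry=self.stoichiometry,
            cholesterol_sites=list(self.cholesterol_sites),
        )

    # -- canonical nucleotide layout (matches the synthetic generator) ------

    def strand_layout(self) -> Dict[str, Dict[str, Tuple[int, int]]]:
        """Domain spans (start, stop) within each strand, 5'->3'.

        Strand A: SE1 | arm_a1 | core | arm_a2 | SE2
        Strand B: SE2* | arm_b1 | core* | arm_b2 | SE1*
        Strand C: one arm's complement.
        """
        se, arm, core = self.se_bp, self.arm_bp, self.core_bp
        spans_ab = {
            "se_head": (0, se),
            "arm1": (se, se + arm),
            "core": (se + arm, se + arm + core),
            "arm2": (se + arm + core, se + arm + core + arm),
            "se_tail": (se + arm + core + arm, se + arm + core + 2 * arm),
        }
        return {"A": spans_ab, "B": dict(spans_ab), "C": {"arm": (0, arm)}}

    def base_pair_map(self, topology: Topology) -> BasePairMap:
        """Design-implied pairing for the canonical F-unit strand order
        [A, B, C1, C2, C3, C4] used by the synthetic generator."""
        lengths = topology.strand_lengths()
        expected = [self.strand_a_len, self.strand_a_len] + [self.arm_bp] * 4
        if list(lengths) != expected:
            raise ValueError(
                f"topology strand lengths {list(lengths)} do not match the "
                f"canonical F-unit layout {expected}"
            )
        offs = np.concatenate([[0], np.cumsum(lengths)])
        spans = self.strand_layout()["A"]
        pairs = []
        # core: A paired antiparallel with B
        a0, b0 = offs[0], offs[1]
        cs, ce = spans["core"]
        for i in range(self.core_bp):
            pairs.append((a0 + cs + i, b0 + cs + (self.core_bp - 1 - i)))
        # arms: A.arm1-C1, A.arm2-C2, B.arm1-C3, B.arm2-C4 (antiparallel)
        arm_spans = [
            (a0, spans["arm1"], offs[2]),
            (a0, spans["arm2"], offs[3]),
            (b0, spans["arm1"], offs[4]),
            (b0, spans["arm2"], offs[5]),
        ]
        for strand_off, (s, _e), c_off in arm_spans:
            for i in range(self.arm_bp):
                pairs.append((strand_off + s + i, c_off + (self.arm_bp - 1 - i)))
        return BasePairMap.from_pairs(pairs, provenance="design")


# ---------------------------------------------------------------------------
# validation report


@dataclass
class CheckResult:
    name: str
    passed: bool
    message: str


@dataclass
class DesignReport:
    checks: List[CheckResult]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> List[CheckResult]:
        return [c for c in self.checks if not c.passed]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {"name": c.name, "passed": c.passed, "message": c.message}
                for c in self.checks
            ],
        }


def _complementarity_check(name, given, expected) -> CheckResult:
    if len(given) != len(expected):
        return CheckResult(
            name, False, f"{name}: length {len(given)} != expected {len(expected)}"
        )
    for k, (g, e) in enumerate(zip(given, expected)):
        if g != e:
            return CheckResult(
                name,
                False,
                f"complementarity check fails in domain {name} at offset {k}: "
                f"found {g}, expected {e}",
            )
    return CheckResult(name, True, "ok")


def validate_design(design: FUnitDesign) -> DesignReport:
    """Check segment lengths, stoichiometry rule, and sticky-end/domain
    complementarity (when sequences are present)."""
    if design is None:
        raise ValueError("design is required")
    checks: List[CheckResult] = []

    ok_lengths = design.core_bp > 0 and design.arm_bp > 0 and design.se_bp > 0
    checks.append(
        CheckResult(
            "segment_lengths",
            ok_lengths,
            f"core {design.core_bp} bp, arm {design.arm_bp} bp, SE {design.se_bp} nt"
            + ("" if ok_lengths else " — all bp counts must be positive"),
        )
    )

    m, n, p = design.stoichiometry
    if m != n:
        checks.append(CheckResult("stoichiometry", False, "m must equal n"))
    elif not math.isclose(p, 10 * m):
        checks.append(CheckResult("stoichiometry", False, "p must equal 10*m"))
    else:
        checks.append(
            CheckResult("stoichiometry", True, f"ABC({m:g}:{n:g}:{p:g}) satisfies m = n = p/10")
        )

    seqs = design.sequences
    if seqs is not None:
        spans = design.strand_layout()["A"]
        a, b, c = seqs.a(), seqs.b(), seqs.c()
        for name, given, expected in (
            ("strand_A_length", a, "x" * design.strand_a_len),
            ("strand_B_length", b, "x" * design.strand_a_len),
            ("strand_C_length", c, "x" * design.arm_bp),
        ):
            checks.append(
                CheckResult(
                    name,
                    len(given) == len(expected),
                    f"{len(given)} nt (expected {len(expected)})",
                )
            )
        if len(a) == len(b) == design.strand_a_len and len(c) == design.arm_bp:
            s, e = spans["se_tail"]
            checks.append(
                _complementarity_check("SE1*", b[s:e], revcomp(a[: design.se_bp]))
            )
            s2, e2 = spans["se_head"]
            checks.append(
                _complementarity_check(
                    "SE2*", b[s2:e2], revcomp(a[spans["se_tail"][0] :])
                )
            )
            cs, ce = spans["core"]
            checks.append(_complementarity_check("core*", b[cs:ce], revcomp(a[cs:ce])))
            for label, strand in (("A", a), ("B", b)):
                for arm_name in ("arm1", "arm2"):
                    s3, e3 = spans[arm_name]
                    checks.append(
                        _complementarity_check(
                            f"{label}.{arm_name}/C", strand[s3:e3], revcomp(c)
                        )
                    )
    return DesignReport(checks)


# ---------------------------------------------------------------------------
# melting thermodynamics


@dataclass
class MeltingConditions:
    """Hybridization conditions: per-strand concentration (M), monovalent
    and divalent cation concentrations (M)."""

    strand_conc_m: float = 1e-6
    monovalent_m: float = 0.15
    divalent_m: float = 0.0

    def validate(self) -> None:
        if self.strand_conc_m <= 0:
            raise ValueError("strand concentration must be positive")
        if self.monovalent_m < 0 or self.divalent_m < 0:
            raise ValueError("salt concentrations must be non-negative")
        if self.monovalent_m == 0 and self.divalent_m == 0:
            raise ValueError("at least one salt concentration must be positive")


@dataclass
class DomainTmSet:
    tm_core: float
    tm_arm: float
    tm_se1: float
    tm_se2: float
    conditions: MeltingConditions

    def as_dict(self) -> Dict[str, float]:
        return {
            "core": self.tm_core,
            "arm": self.tm_arm,
            "se1": self.tm_se1,
            "se2": self.tm_se2,
        }


def duplex_tm(sequence: str, conditions: MeltingConditions = MeltingConditions()) -> float:
    """Nearest-neighbor melting temperature (°C) of a duplex formed by
    ``sequence`` and its exact complement at equal strand concentrations.

    Unified SantaLucia-2004 parameters; entropy-based monovalent salt
    correction with divalent cations folded in as an equivalent
    monovalent concentration (120*sqrt([Mg2+]) in mM).
    """
    conditions.validate()
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("domain shorter than 2 nt has no nearest-neighbor stack")
    if any(b not in "ACGT" for b in seq):
        bad = next(b for b in seq if b not in "ACGT")
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    c_nm = conditions.strand_conc_m * 1e9
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN4,
            dnac1=c_nm,
            dnac2=c_nm,
            Na=conditions.monovalent_m * 1e3,
            Mg=conditions.divalent_m * 1e3,
            saltcorr=5,
            selfcomp=False,
        )
    )


def domain_melting_temperatures(
    design: FUnitDesign, conditions: MeltingConditions = MeltingConditions()
) -> DomainTmSet:
    """Tm of each duplex domain (core, arm, SE1, SE2) of the design."""
    if design.sequences is None:
        raise ValueError(
            "design has no sequences; use design.with_random_sequences(seed) "
            "or supply a DesignSequences"
        )
    s = design.sequences
    return DomainTmSet(
        tm_core=duplex_tm(s.core, conditions),
        tm_arm=duplex_tm(s.arm, conditions),
        tm_se1=duplex_tm(s.se1, conditions),
        tm_se2=duplex_tm(s.se2, conditions),
        conditions=conditions,
    )


# ---------------------------------------------------------------------------
# annealing protocols


def _ramp(t_from: float, t_to: float, step_minutes: float = 5.0) -> List[Tuple[float, float]]:
    """Expand a -1 °C / 5 min ramp into stepwise 1 °C holds, excluding both
    endpoint temperatures (they are explicit holds in the schedules)."""
    lo, hi = min(t_from, t_to), max(t_from, t_to)
    temps = np.arange(hi - 1, lo, -1.0) if t_from > t_to else np.arange(lo + 1, hi, 1.0)
    return [(float(t), step_minutes) for t in temps]


@dataclass
class AnnealingProtocol:
    """Stepped temperature schedule; ramps pre-expanded to 1 °C holds."""

    name: str
    steps: List[Tuple[float, float]]  # (temperature °C, duration minutes)

    def __post_init__(self):
        if not self.steps:
            raise ValueError("protocol must hold at least one step")
        if any(d <= 0 for _t, d in self.steps):
            raise ValueError("step durations must be positive")

    @property
    def total_minutes(self) -> float:
        return float(sum(d for _t, d in self.steps))

    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for _t, d in self.steps])[:-1]])

    @classmethod
    def named(cls, name: str) -> "AnnealingProtocol":
        """The five named experimental schedules (fast protocols A/B/C differ only
        in the final 25 °C hold; slow protocols in the final 4 °C hold)."""
        key = name.upper().replace("_", "-")
        fast_head = [(90.0, 5.0), (68.0, 10.0), (59.0, 10.0), (42.0, 60.0)]
        slow_head = (
            [(90.0, 5.0)]
            + _ramp(90, 68)
            + [(68.0, 180.0)]
            + _ramp(68, 59)
            + [(59.0, 180.0)]
            + _ramp(59, 42)
            + [(42.0, 360.0)]
            + _ramp(42, 40)
            + [(40.0, 360.0)]
        )
        table = {
            "FAP-A": fast_head + _ramp(42, 25) + [(25.0, 30.0)],
            "FAP-B": fast_head + _ramp(42, 25) + [(25.0, 60.0)],
            "FAP-C": fast_head + _ramp(42, 25) + [(25.0, 24 * 60.0)],
            "SAP-A": slow_head + [(4.0, 2.0)],
            "SAP-B": slow_head + [(4.0, 60.0)],
        }
        if key not in table:
            raise ValueError(f"unknown protocol {name!r}; known: {sorted(table)}")
        return cls(name=key, steps=table[key])


@dataclass
class HybridizationEvent:
    domain: str
    time_min: float
    temperature_c: float


@dataclass
class AssemblyOrder:
    events: List[HybridizationEvent]
    unbound: List[str]

    def domain_order(self) -> List[str]:
        return [e.domain for e in self.events]


def assembly_order(tms: DomainTmSet, protocol: AnnealingProtocol) -> AssemblyOrder:
    """Hybridization events under a sharp-threshold model: a domain binds
    at the first schedule time its temperature falls to or below its Tm."""
    starts = protocol.start_times()
    events: List[HybridizationEvent] = []
    unbound: List[str] = []
    for domain, tm in tms.as_dict().items():
        hit = next(
            (
                (float(starts[k]), float(t))
                for k, (t, _d) in enumerate(protocol.steps)
                if t <= tm
            ),
            None,
        )
        if hit is None:
            unbound.append(domain)
        else:
            events.append(HybridizationEvent(domain, hit[0], hit[1]))
    events.sort(key=lambda e: e.time_min)
    return AssemblyOrder(events, unbound)


# ---------------------------------------------------------------------------
# idealized geometry


@dataclass
class LatticeGeometry:
    side_long_bp: int
    side_short_bp: int
    side_long_nm: float
    side_short_nm: float
    junction_angle_deg: float
    diag_long_nm: float
    diag_short_nm: float
    porosity_fraction: float


@dataclass
class IdealUnitModel:
    """Center-line model of one F-unit: junctions, arm directions,
    segment endpoints, cholesterol attachment coordinates."""

    junctions: Tuple[np.ndarray, np.ndarray]
    arm_directions: Dict[str, np.ndarray]  # e1..e6, unit vectors
    segments: Dict[str, Tuple[np.ndarray, np.ndarray]]
    cholesterol_sites: Dict[str, np.ndarray]
    design: FUnitDesign

    def junction_tripod(self, junction: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if junction == 1:
            return tuple(self.arm_directions[k] for k in ("e1", "e2", "e3"))
        if junction == 2:
            return tuple(self.arm_directions[k] for k in ("e4", "e5", "e6"))
        raise ValueError("junction must be 1 or 2")


def _tripod(a12: float, a13: float, a23: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit vectors (e1, e2, e3) realizing the three pairwise angles
    exactly, with e3 and e1 in the z = 0 plane.

    A coplanar tripod exists only when the angles sum to 360° (or one
    angle equals the sum of the others); otherwise e2 acquires the
    minimal out-of-plane component.  Angles in degrees.
    """
    for a in (a12, a13, a23):
        if not 0 < a < 180:
            raise ValueError("inter-arm angles must lie strictly between 0 and 180 deg")
    if a12 + a13 + a23 > 360 + 1e-9:
        raise ValueError("impossible angle set: per-junction angles sum above 360 deg")
    r12, r13, r23 = np.deg2rad([a12, a13, a23])
    e3 = np.array([1.0, 0.0, 0.0])
    e1 = np.array([np.cos(r13), np.sin(r13), 0.0])
    x = np.cos(r23)
    y = (np.cos(r12) - x * np.cos(r13)) / np.sin(r13)
    z2 = 1.0 - x * x - y * y
    if z2 < -1e-9:
        raise ValueError(
            "impossible angle set: no unit tripod realizes "
            f"({a12}, {a13}, {a23}) deg"
        )
    z = 0.0 if z2 < 1e-12 else math.sqrt(z2)
    e2 = np.array([x, y, z])
    return e1, e2, e3


def build_ideal_funit(
    design: FUnitDesign,
    junction_angles: Tuple[float, float, float] = (80.0, 150.0, 120.0),
) -> IdealUnitModel:
    """Center-line model with the core along +x and arms placed so the
    pairwise junction angles (α12, α13, α23) = ``junction_angles`` are
    reproduced exactly (α13/α23 against the core direction e3/e6).

    With the defaults taken from the equilibrated coarse-grained
    simulations — (80°, 150°, 120°), summing to 350° — each junction is
    minimally non-planar; an angle set summing to 360° yields an exactly
    planar (z = 0) build.
    """
    a12, a13, a23 = junction_angles
    e1, e2, e3 = _tripod(a12, a13, a23)
    core_len = design.core_bp * design.rise_nm
    arm_len = design.arm_bp * design.rise_nm
    se_len = design.se_bp * design.rise_nm
    j1 = np.zeros(3)
    j2 = np.array([core_len, 0.0, 0.0])
    # junction 2 tripod is the junction 1 tripod rotated 180° about z, so
    # e6 (core direction seen from J2) is -x
    flip = np.diag([-1.0, -1.0, 1.0])
    e4, e5, e6 = (flip @ e1, flip @ e2, flip @ e3)
    dirs = {"e1": e1, "e2": e2, "e3": e3, "e4": e4, "e5": e5, "e6": e6}
    segments = {
        "core": (j1, j2),
        "arm_e1": (j1, j1 + arm_len * e1),
        "arm_e2": (j1, j1 + arm_len * e2),
        "arm_e4": (j2, j2 + arm_len * e4),
        "arm_e5": (j2, j2 + arm_len * e5),
        "se_e1": (j1 + arm_len * e1, j1 + (arm_len + se_len) * e1),
        "se_e2": (j1 + arm_len * e2, j1 + (arm_len + se_len) * e2),
        "se_e4": (j2 + arm_len * e4, j2 + (arm_len + se_len) * e4),
        "se_e5": (j2 + arm_len * e5, j2 + (arm_len + se_len) * e5),
    }
    # cholesterol: distal arm terminus on e1/e4-type arms, junction-proximal
    # terminus on e2/e5-type arms
    chol = {
        "e1": j1 + arm_len * e1,
        "e2": j1.copy(),
        "e4": j2 + arm_len * e4,
        "e5": j2.copy(),
    }
    return IdealUnitModel(
        junctions=(j1, j2),
        arm_directions=dirs,
        segments=segments,
        cholesterol_sites=chol,
        design=design,
    )


def parallelogram_diagonals(a: float, b: float, theta_deg: float) -> Tuple[float, float]:
    """(long, short) diagonals of a parallelogram with sides a, b at angle
    theta: d = sqrt(a^2 + b^2 ± 2ab cosθ)."""
    th = np.deg2rad(theta_deg)
    d_plus = math.sqrt(a * a + b * b + 2 * a * b * math.cos(th))
    d_minus = math.sqrt(a * a + b * b - 2 * a * b * math.cos(th))
    return max(d_plus, d_minus), min(d_plus, d_minus)


def lattice_porosity(
    side_long_nm: float,
    side_short_nm: float,
    junction_angle_deg: float,
    duplex_width_nm: float = DUPLEX_WIDTH_NM,
) -> float:
    """Open-area fraction of the parallelogram unit cell.

    Each cell owns one long-side duplex strip and one short-side strip
    minus their corner overlap: φ = 1 − (a + b − w)·w / (a·b·sinθ).
    """
    a, b, w = side_long_nm, side_short_nm, duplex_width_nm
    if a <= 0 or b <= 0:
        raise ValueError("side lengths must be positive")
    if not 0 < junction_angle_deg < 180:
        raise ValueError("junction angle must lie in (0, 180) deg")
    if w >= min(a, b):
        raise ValueError("duplex width must be smaller than both sides")
    th = np.deg2rad(junction_angle_deg)
    return 1.0 - (a + b - w) * w / (a * b * math.sin(th))


def pore_lattice_geometry(
    design: FUnitDesign, junction_angle_deg: float = 80.0
) -> LatticeGeometry:
    """Idealized pore lattice: side contour lengths from the design,
    parallelogram diagonals at the junction angle, and porosity."""
    if not 0 < junction_angle_deg < 180:
        raise ValueError("junction angle must lie in (0, 180) deg")
    a = design.side_long_bp * design.rise_nm
    b = design.side_short_bp * design.rise_nm
    d_long, d_short = parallelogram_diagonals(a, b, junction_angle_deg)
    phi = lattice_porosity(a, b, junction_angle_deg, design.duplex_width_nm)
    return LatticeGeometry(
        side_long_bp=design.side_long_bp,
        side_short_bp=design.side_short_bp,
        side_long_nm=a,
        side_short_nm=b,
        junction_angle_deg=junction_angle_deg,
        diag_long_nm=d_long,
        diag_short_nm=d_short,
        porosity_fraction=phi,
    )


@dataclass
class CholesterolSpacings:
    min_nm: float
    max_nm: float
    pairwise_nm: np.ndarray
    site_labels: List[str]
    site_points: np.ndarray


def cholesterol_spacings(
    design: FUnitDesign,
    lattice: Optional[LatticeGeometry] = None,
    junction_angle_deg: float = 80.0,
) -> CholesterolSpacings:
    """Cholesterol-to-cholesterol distances in the ideal collinear-segment
    lattice neighborhood (one junction pair plus its four sticky-end
    bridged neighbor arms).

    The minimum is between the two distal attachment sites facing each
    other across a sticky-end bridge (≈ se_bp × rise); the maximum is
    between junction-proximal sites across a full arm–SE–arm path
    (≈ (2·arm_bp + se_bp) × rise).
    """
    if not design.cholesterol_sites:
        raise ValueError("design defines no cholesterol sites")
    if lattice is not None:
        junction_angle_deg = lattice.junction_angle_deg
    rise = design.rise_nm
    arm, se = design.arm_bp * rise, design.se_bp * rise
    core = design.core_bp * rise
    th = np.deg2rad(junction_angle_deg)
    u = np.array([1.0, 0.0, 0.0])  # long-side direction (collinear with core)
    v = np.array([math.cos(th), math.sin(th), 0.0])  # short-side direction

    # central junction pair: J1 at origin, core to J2 along +u
    j1, j2 = np.zeros(3), core * u
    sites: List[Tuple[str, np.ndarray, str, str]] = []  # label, point, kind, bridge

    def bridge(tag: str, origin: np.ndarray, direction: np.ndarray, kind: str):
        """One arm-SE-arm connection from ``origin`` along ``direction``;
        attachment sites depend on whether the bridged arms carry their
        cholesterol at the distal or the junction-proximal terminus."""
        if kind == "distal":
            sites.append((f"{tag}.near", origin + arm * direction, "distal", tag))
            sites.append((f"{tag}.far", origin + (arm + se) * direction, "distal", tag))
        else:
            sites.append((f"{tag}.near", origin.copy(), "proximal", tag))
            sites.append(
                (f"{tag}.far", origin + (2 * arm + se) * direction, "proximal", tag)
            )

    # e1/e4-type arms continue the long side (aligned with the core) and
    # carry distal cholesterols; e2/e5-type arms run along the short side
    # and carry junction-proximal cholesterols
    bridge("J1.e1", j1, -u, "distal")
    bridge("J2.e4", j2, +u, "distal")
    bridge("J1.e2", j1, -v, "proximal")
    bridge("J2.e5", j2, +v, "proximal")

    pts = np.array([p for _l, p, _k, _b in sites])
    labels = [l for l, _p, _k, _b in sites]
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)

    same_bridge = [
        (i, j)
        for i in range(len(sites))
        for j in range(i + 1, len(sites))
        if sites[i][3] == sites[j][3]
    ]
    min_nm = min(dist[i, j] for i, j in same_bridge if sites[i][2] == "distal")
    max_nm = max(dist[i, j] for i, j in same_bridge if sites[i][2] == "proximal")
    return CholesterolSpacings(
        min_nm=float(min_nm),
        max_nm=float(max_nm),
        pairwise_nm=dist,
        site_labels=labels,
        site_points=pts,
    )
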