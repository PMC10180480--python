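"""Interfacial shear rheology sweeps and bulk-modulus extrapolation.

A Du Nouy-ring time sweep records the interfacial storage and loss shear
moduli G' and G'' (N/m) of a liquid/liquid interface as the nanosheet
assembles and anneals.  The sweep is segmented into protocol phases
(strand additions, heating above the sticky-end melting temperature,
cooling) and each phase is summarized by its trailing plateau.

The interfacial storage modulus extrapolates to a volumetric Young's
modulus through the standard isotropic shear-to-Young relation applied
to a sheet of thickness t:

    E = 2 (1 + ν) · G' / t

with ν = 0.5 (incompressible) and t = 2 nm (one duplex diameter) by
default.  Because a fraction φ of the sheet area is open pore, the
modulus of the load-bearing DNA itself is at least E / (1 − φ).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RheologySweep",
    "ExtrapolationParams",
    "ExtrapolationResult",
    "PhaseStats",
    "read_time_sweep",
    "write_time_sweep",
    "segment_time_sweep",
    "bulk_young_modulus",
    "porosity_corrected_modulus",
    "elastic_gap_orders",
    "extrapolate",
]

#: accepted column aliases -> canonical name
_COLUMN_ALIASES = {
    "time": "time_s",
    "time_s": "time_s",
    "gp": "Gp_N_per_m",
    "gp_n_per_m": "Gp_N_per_m",
    "gpp": "Gpp_N_per_m",
    "gpp_n_per_m": "Gpp_N_per_m",
    "temperature": "temperature_C",
    "temperature_c": "temperature_C",
    "frequency_hz": "frequency_Hz",
    "frequency": "frequency_Hz",
    "strain": "strain",
    "phase": "phase",
}
_HUMAN_NAMES = {
    "time_s": "time",
    "Gp_N_per_m": "storage_modulus",
    "Gpp_N_per_m": "loss_modulus",
    "temperature_C": "temperature",
}


@dataclass
class RheologySweep:
    """Interfacial time sweep; SI units (s, N/m, °C)."""

    time_s: np.ndarray
    storage_modulus: np.ndarray  # G', N/m
    loss_modulus: np.ndarray  # G'', N/m
    temperature_c: np.ndarray
    frequency_hz: Optional[np.ndarray] = None
    strain: Optional[np.ndarray] = None
    phase_labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.storage_modulus = np.asarray(self.storage_modulus, dtype=float)
        self.loss_modulus = np.asarray(self.loss_modulus, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        n = len(self.time_s)
        for name in ("storage_modulus", "loss_modulus", "temperature_c"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")
        if n > 1 and not (np.diff(self.time_s) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (self.storage_modulus < 0).any() or (self.loss_modulus < 0).any():
            raise ValueError("moduli must be non-negative")

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_s": self.time_s,
            "Gp_N_per_m": self.storage_modulus,
            "Gpp_N_per_m": self.loss_modulus,
            "temperature_C": self.temperature_c,
        }
        if self.frequency_hz is not None:
            data["frequency_Hz"] = self.frequency_hz
        if self.strain is not None:
            data["strain"] = self.strain
        if self.phase_labels is not None:
            data["phase"] = self.phase_labels
        return pd.DataFrame(data)


def read_time_sweep(path) -> RheologySweep:
    """Read a delimited sweep table (columns time, Gp, Gpp, temperature;
    long canonical names accepted)."""
    df = pd.read_csv(path)
    df.columns = [
        _COLUMN_ALIASES.get(c.strip().lower(), c.strip()) for c in df.columns
    ]
    for col in ("time_s", "Gp_N_per_m", "Gpp_N_per_m", "temperature_C"):
        if col not in df.columns:
            raise ValueError(f"{_HUMAN_NAMES[col]} column absent")
    return RheologySweep(
        time_s=df["time_s"].to_numpy(),
        storage_modulus=df["Gp_N_per_m"].to_numpy(),
        loss_modulus=df["Gpp_N_per_m"].to_numpy(),
        temperature_c=df["temperature_C"].to_numpy(),
        frequency_hz=df["frequency_Hz"].to_numpy() if "frequency_Hz" in df else None,
        strain=df["strain"].to_numpy() if "strain" in df else None,
        phase_labels=df["phase"].to_numpy() if "phase" in df else None,
    )


def write_time_sweep(sweep: RheologySweep, path) -> None:
    sweep.to_frame().to_csv(path, index=False)


@dataclass
class PhaseStats:
    """Trailing-window plateau summary of one protocol phase."""

    start_s: float
    end_s: float
    mean_storage: float
    mean_loss: float
    n_window: int
    label: Optional[str] = None


def segment_time_sweep(
    sweep: RheologySweep,
    boundaries_s: Optional[Sequence[float]] = None,
    temperature_trigger_c: Optional[float] = None,
    trailing_fraction: float = 0.25,
) -> List[PhaseStats]:
    """Split a sweep into phases and summarize each by trailing-window
    plateau means.

    Phases come either from explicit boundary times or from crossings of
    a temperature trigger (each change of the ``T >= trigger`` state
    opens a new phase).  The plateau is the mean over the trailing
    ``trailing_fraction`` of each phase's samples.
    """
    if not 0 < trailing_fraction <= 1:
        raise ValueError("trailing_fraction must lie in (0, 1]")
    t = sweep.time_s
    if temperature_trigger_c is not None:
        above = sweep.temperature_c >= temperature_trigger_c
        change = np.where(above[1:] != above[:-1])[0] + 1
        cut_idx = list(change)
    elif boundaries_s is not None:
        boundaries_s = sorted(boundaries_s)
        if boundaries_s and (
            boundaries_s[0] <= t[0] or boundaries_s[-1] >= t[-1]
        ):
            raise ValueError("phase boundaries must lie strictly inside the time range")
        cut_idx = [int(np.searchsorted(t, b)) for b in boundaries_s]
    else:
        cut_idx = []
    edges = [0] + cut_idx + [len(t)]
    phases: List[PhaseStats] = []
    for k, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        if b <= a:
            raise ValueError(f"phase {k} is empty")
        n_win = max(int(np.ceil((b - a) * trailing_fraction)), 1)
        sl = slice(b - n_win, b)
        label = None
        if sweep.phase_labels is not None:
            label = str(sweep.phase_labels[a])
        phases.append(
            PhaseStats(
                start_s=float(t[a]),
                end_s=float(t[b - 1]),
                mean_storage=float(sweep.storage_modulus[sl].mean()),
                mean_loss=float(sweep.loss_modulus[sl].mean()),
                n_window=n_win,
                label=label,
            )
        )
    return phases


@dataclass
class ExtrapolationParams:
    """Sheet thickness (nm), Poisson ratio, and open-area porosity used to
    convert an interfacial shear modulus into bulk Young's moduli."""

    thickness_nm: float = 2.0
    poisson_ratio: float = 0.5
    porosity_fraction: float = 0.40

    def __post_init__(self):
        if self.thickness_nm <= 0:
            raise ValueError("thickness must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if not 0 <= self.porosity_fraction < 1:
            raise ValueError("porosity must lie in [0, 1)")


@dataclass
class ExtrapolationResult:
    bulk_young_modulus_pa: float
    porosity_corrected_modulus_pa: float
    interfacial_storage_n_per_m: float
    params: ExtrapolationParams

    @property
    def bulk_young_modulus_mpa(self) -> float:
        return self.bulk_young_modulus_pa / 1e6

    @property
    def porosity_corrected_modulus_mpa(self) -> float:
        return self.porosity_corrected_modulus_pa / 1e6


def bulk_young_modulus(gs_n_per_m: float, params: ExtrapolationParams) -> float:
    """E = 2 (1 + ν) G' / t in Pa, for G' in N/m and thickness in nm."""
    if gs_n_per_m < 0:
        raise ValueError("interfacial storage modulus must be non-negative")
    t_m = params.thickness_nm * 1e-9
    return 2.0 * (1.0 + params.poisson_ratio) * gs_n_per_m / t_m


def porosity_corrected_modulus(e_pa: float, porosity_fraction: float) -> float:
    """Lower-bound modulus of the load-bearing fraction: E / (1 − φ)."""
    if not 0 <= porosity_fraction < 1:
        raise ValueError("porosity must lie in [0, 1)")
    return e_pa / (1.0 - porosity_fraction)


def elastic_gap_orders(gp_n_per_m: float, gpp_n_per_m: float) -> float:
    """Storage/loss gap in decades: log10(G'/G'')."""
    if gp_n_per_m <= 0 or gpp_n_per_m <= 0:
        raise ValueError("moduli must be positive to compute a log gap")
    return math.log10(gp_n_per_m / gpp_n_per_m)


def extrapolate(gs_n_per_m: float, params: Optional[ExtrapolationParams] = None) -> ExtrapolationResult:
    """Chain the bulk extrapolation and the porosity correction."""
    params = params or ExtrapolationParams()
    e = bulk_young_modulus(gs_n_per_m, params)
    return ExtrapolationResult(
        bulk_young_modulus_pa=e,
        porosity_corrected_modulus_pa=porosity_corrected_modulus(
            e, params.porosity_fraction
        ),
        interfacial_storage_n_per_m=gs_n_per_m,
        params=params,
    )
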