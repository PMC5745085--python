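"""Reaction networks for Vg1-Nodal dimerization kinetics.

Two mass-action schemes describe how the active dimer ligand forms in the
early zebrafish embryo:

*Primed heterodimer model.*  A maternal pool of Vg1 monomer (``V``) is
deposited before fertilization.  Zygotic Nodal monomer (``N``) is produced
constitutively during a fixed developmental window and pairs with Vg1::

    dN/dt = lambda_N(t) - beta_N * N - lambda_D * N * V
    dV/dt =             - beta_V * V - lambda_D * N * V
    dD/dt =                            lambda_D * N * V

*Cold-start homodimer model.*  No Vg1 is present; Nodal must accumulate and
homodimerize::

    dN/dt = lambda_N(t) - beta_N * N - lambda_D * N**2
    dD/dt =                            lambda_D * N**2

Both schemes share constitutive windowed synthesis of N, first-order
degradation of monomers, and an irreversible bimolecular dimerization step.
Note that the cold-start scheme, as written, converts one unit of N into one
unit of D; this bookkeeping is kept exactly (see the methods note) and the
stochastic twin in :mod:`vgnodal.stochastic` is built to share its mean field.

All quantities are SI internally: concentrations in molar (M), times in
seconds.  User-facing I/O uses nM and hours post-fertilization (hpf);
conversion constants live here.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass

__all__ = [
    "M_PER_NM",
    "S_PER_HPF",
    "AVOGADRO",
    "ModelKind",
    "KineticParameters",
    "SystemState",
    "default_parameters",
    "production_rate",
    "rhs_primed",
    "rhs_cold_start",
]

#: Exact unit conversions: 1 nM = 1e-9 M, 1 hpf = 3600 s.
M_PER_NM = 1e-9
S_PER_HPF = 3600.0

#: Avogadro's number (exact, 2019 SI), used for count<->concentration mapping.
AVOGADRO = 6.02214076e23


class ModelKind(str, enum.Enum):
    """Which reaction network applies.

    ``PRIMED_HETERODIMER``: maternal Vg1 pool present, D is the Vg1-Nodal
    heterodimer.  ``COLD_START_HOMODIMER``: no Vg1, D is the Nodal-Nodal
    homodimer and V is fixed at zero and inert.
    """

    PRIMED_HETERODIMER = "primed"
    COLD_START_HOMODIMER = "cold_start"


# Serialization key -> (field, to-SI factor).  Rates are serialized in SI,
# the Vg1 pool in nM and the window times in hpf, mirroring how the values
# are conventionally quoted.
_SERIAL_KEYS = {
    "lambda_N_on_M_per_s": ("lambda_N_on", 1.0),
    "beta_N_per_s": ("beta_N", 1.0),
    "beta_V_per_s": ("beta_V", 1.0),
    "lambda_D_per_M_per_s": ("lambda_D", 1.0),
    "V0_nM": ("V0", M_PER_NM),
    "t_on_hpf": ("t_on", S_PER_HPF),
    "t_off_hpf": ("t_off", S_PER_HPF),
    "t_end_hpf": ("t_end", S_PER_HPF),
}


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, maternal Vg1 pool, and the Nodal production window.

    Parameters
    ----------
    lambda_N_on
        Nodal synthesis rate while production is on (M s^-1).
    beta_N, beta_V
        First-order degradation rates of the Nodal and Vg1 monomers (s^-1);
        the corresponding half-lives are ln2/beta.
    lambda_D
        Bimolecular dimerization rate (M^-1 s^-1), shared by the
        heterodimerization and homodimerization steps.
    V0
        Maternally deposited Vg1 concentration at t = 0 (M).
    t_on, t_off
        Start and end of the Nodal production window (s).  Defaults are
        4 hpf (onset of zygotic transcription) and 6 hpf (end of
        mesendodermal patterning).
    t_end
        Simulation horizon (s), default 10 hpf.
    """

    lambda_N_on: float = 2e-13
    beta_N: float = 1.16e-4
    beta_V: float = 1.16e-4
    lambda_D: float = 1e6
    V0: float = 100 * M_PER_NM
    t_on: float = 4 * S_PER_HPF
    t_off: float = 6 * S_PER_HPF
    t_end: float = 10 * S_PER_HPF

    def __post_init__(self) -> None:
        for name in ("lambda_N_on", "beta_N", "beta_V", "lambda_D", "V0"):
            value = getattr(self, name)
            if not value >= 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if not (0 <= self.t_on < self.t_off <= self.t_end):
            raise ValueError(
                "window must satisfy 0 <= t_on < t_off <= t_end, got "
                f"t_on={self.t_on}, t_off={self.t_off}, t_end={self.t_end}"
            )

    def replace(self, **changes: float) -> "KineticParameters":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        """Flat mapping using the declared serialization keys and units."""
        return {
            key: getattr(self, field) / factor
            for key, (field, factor) in _SERIAL_KEYS.items()
        }

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "KineticParameters":
        unknown = set(data) - set(_SERIAL_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        kwargs = {
            field: float(data[key]) * factor
            for key, (field, factor) in _SERIAL_KEYS.items()
            if key in data
        }
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "KineticParameters":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SystemState:
    """Instantaneous concentrations (M) of the three species.

    ``V`` is fixed at zero and inert for the cold-start model.
    """

    N: float
    V: float
    D: float

    def __post_init__(self) -> None:
        for name in ("N", "V", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")


def default_parameters() -> KineticParameters:
    """The published parameterization of both networks.

    lambda_N_on = 2e-13 M/s, beta_N = beta_V = 1.16e-4 /s,
    lambda_D = 1e6 /M/s, V0 = 100 nM, production window 4-6 hpf,
    horizon 10 hpf.
    """
    return KineticParameters()


def production_rate(t: float, params: KineticParameters) -> float:
    """Piecewise-constant Nodal synthesis rate lambda_N(t) in M s^-1.

    Returns ``lambda_N_on`` strictly inside the window ``(t_on, t_off)`` and
    zero elsewhere, including at the boundary instants themselves (a fixed
    measure-zero convention; the integral is unaffected).
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return params.lambda_N_on if params.t_on < t < params.t_off else 0.0


def rhs_primed(
    t: float, state: SystemState, params: KineticParameters
) -> tuple[float, float, float]:
    """Time derivatives (dN/dt, dV/dt, dD/dt) of the primed heterodimer model."""
    pair_flux = params.lambda_D * state.N * state.V
    dN = production_rate(t, params) - params.beta_N * state.N - pair_flux
    dV = -params.beta_V * state.V - pair_flux
    dD = pair_flux
    return dN, dV, dD


def rhs_cold_start(
    t: float, state: SystemState, params: KineticParameters
) -> tuple[float, float]:
    """Time derivatives (dN/dt, dD/dt) of the cold-start homodimer model.

    One unit of N is converted per unit of D formed, exactly as the scheme
    is written; ``state.V`` is ignored.
    """
    homo_flux = params.lambda_D * state.N * state.N
    dN = production_rate(t, params) - params.beta_N * state.N - homo_flux
    dD = homo_flux
    return dN, dD
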