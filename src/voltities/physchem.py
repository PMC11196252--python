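"""Speciation, ionic partition diagrams and derived physicochemical constants.

The science
-----------
An ionizable drug such as a fluoroquinolone carries a carboxylic acid
(pKa1 ~ 6) and a basic piperazine nitrogen (pKa2 ~ 8.5).  Its half-wave
transfer potential across a polarizable water | 1,2-dichloroethane
interface therefore depends on pH: below both pKa values the molecule is a
cation and transfers at its formal potential phi0; as the pH approaches
pKa2 the neutral/zwitterionic form partitions into the organic phase
(distribution constant K_D) and the half-wave potential rises, reaching a
Nernstian ~59 mV per pH unit asymptote.  The closed form is

    phi_1/2(pH) = phi0 + (R*T / (z*F)) * ln( (10^-pH + Ka*K_D + Ka) / 10^-pH )

with Ka = 10^-pKa2.  K_D here is the organic-favouring ratio
[drug]_org / [drug]_aq of the neutral form: a larger K_D produces a larger
high-pH shift, which is the orientation required for the diagram to bend
upward.  (The inverse, water-favouring convention is available through the
``invert`` flag of :func:`fit_partition_model`.)

The formal transfer potential of the cation maps onto standard
lipophilicity scales:

    logP'_water/org = -phi0 * z * F / (2.303 * R * T)
    dG'_aq->org     =  z * F * phi0          (J mol^-1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core import F, R, T_DEFAULT, nernst_slope

__all__ = [
    "SpeciationProfile",
    "PartitionModel",
    "PhysChemConstants",
    "speciation_fractions",
    "partition_halfwave",
    "fit_partition_model",
    "logp_from_phi",
    "gibbs_from_phi",
]

#: danofloxacin acid-dissociation constants (carboxylic acid, piperazinium)
PKA1_DANO: float = 6.07
PKA2_DANO: float = 8.50


# ---------------------------------------------------------------------------
# Speciation
# ---------------------------------------------------------------------------


@dataclass
class SpeciationProfile:
    """pH-resolved microspecies fractions of a diprotic amphoteric molecule.

    ``f_cation`` is the fully protonated (cationic) form, ``f_neutral`` the
    neutral/zwitterionic form and ``f_anion`` the deprotonated (anionic)
    form.  At every pH the three fractions sum to one.
    """

    pH: np.ndarray
    f_cation: np.ndarray
    f_neutral: np.ndarray
    f_anion: np.ndarray
    pKa1: float
    pKa2: float

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.f_cation = np.asarray(self.f_cation, dtype=float)
        self.f_neutral = np.asarray(self.f_neutral, dtype=float)
        self.f_anion = np.asarray(self.f_anion, dtype=float)
        if self.pKa1 >= self.pKa2:
            raise ValueError(
                f"pKa1 must be < pKa2, got {self.pKa1} >= {self.pKa2}"
            )
        total = self.f_cation + self.f_neutral + self.f_anion
        if not np.allclose(total, 1.0, rtol=0, atol=1e-12):
            raise ValueError("microspecies fractions must sum to 1 at every pH")
        for frac in (self.f_cation, self.f_neutral, self.f_anion):
            if np.any(frac < 0) or np.any(frac > 1):
                raise ValueError("fractions must lie in [0, 1]")


def speciation_fractions(
    pH_grid, pKa1: float = PKA1_DANO, pKa2: float = PKA2_DANO
) -> SpeciationProfile:
    """Closed-form diprotic speciation.

    With h = 10^-pH and Ka_i = 10^-pKa_i the denominator is
    h^2 + Ka1*h + Ka1*Ka2 and

        f_cation  = h^2       / den
        f_neutral = Ka1*h     / den
        f_anion   = Ka1*Ka2   / den

    The neutral fraction peaks exactly at pH = (pKa1 + pKa2) / 2.
    """
    pH = np.atleast_1d(np.asarray(pH_grid, dtype=float))
    if np.any(pH < 0) or np.any(pH > 14):
        raise ValueError("pH grid must lie within [0, 14]")
    if pKa1 >= pKa2:
        raise ValueError(f"pKa1 must be < pKa2, got {pKa1} >= {pKa2}")
    h = 10.0 ** (-pH)
    ka1 = 10.0 ** (-pKa1)
    ka2 = 10.0 ** (-pKa2)
    den = h * h + ka1 * h + ka1 * ka2
    return SpeciationProfile(
        pH=pH,
        f_cation=h * h / den,
        f_neutral=ka1 * h / den,
        f_anion=ka1 * ka2 / den,
        pKa1=pKa1,
        pKa2=pKa2,
    )


# ---------------------------------------------------------------------------
# Ionic partition diagram
# ---------------------------------------------------------------------------


@dataclass
class PartitionModel:
    """Parameters of the ionic-partition-diagram model.

    Attributes
    ----------
    phi0
        Formal transfer potential of the cation, V.
    pKa
        Acid dissociation exponent entering the diagram (the piperazinium
        pKa2 for a fluoroquinolone); ``Ka = 10^-pKa``.
    K_D
        Distribution constant of the neutral form, organic-favouring
        ([drug]_org / [drug]_aq).  Must be positive.
    z
        Charge of the transferring ion (+1 for the protonated drug).
    T
        Temperature in kelvin.
    """

    phi0: float
    pKa: float
    K_D: float
    z: int = 1
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ValueError(f"K_D must be > 0, got {self.K_D}")
        if not (0.0 < self.Ka < 1.0):
            raise ValueError(f"Ka = 10^-pKa must lie in (0, 1), got pKa={self.pKa}")
        if self.z == 0:
            raise ValueError("charge z must be nonzero")
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def Ka(self) -> float:
        return 10.0 ** (-self.pKa)


def partition_halfwave(pH, model: PartitionModel):
    """Half-wave transfer potential at the given pH (scalar or array), V.

    Low-pH limit: phi0 (pure cation transfer).  High-pH asymptote: slope of
    one Nernstian unit (2.303*R*T/zF) per pH.
    """
    pH_arr = np.asarray(pH, dtype=float)
    h = 10.0 ** (-pH_arr)
    ka = model.Ka
    shift = (R * model.T / (model.z * F)) * np.log((h + ka * model.K_D + ka) / h)
    out = model.phi0 + shift
    return float(out) if np.ndim(pH) == 0 else out


def _halfwave_shift(pH: np.ndarray, pKa: float, K_D: float, z: int, T: float):
    h = 10.0 ** (-np.asarray(pH, dtype=float))
    ka = 10.0 ** (-pKa)
    return (R * T / (z * F)) * np.log((h + ka * K_D + ka) / h)


def fit_partition_model(
    data,
    pKa: float,
    fit_phi0: bool = True,
    phi0: float | None = None,
    z: int = 1,
    T: float = T_DEFAULT,
    invert: bool = False,
) -> tuple[PartitionModel, dict]:
    """Least-squares fit of K_D (and optionally phi0) to (pH, phi_1/2) data.

    The search runs over log10(K_D) on a coarse grid from -2 to 6 and is
    then refined locally with bounded scalar minimization; for a candidate
    K_D the optimal phi0 is the analytic mean residual, so the problem is
    one-dimensional.

    Parameters
    ----------
    data
        Iterable of ``(pH, half_wave_potential_V)`` pairs; at least 5
        points spanning the flat and rising branches are recommended.
    pKa
        Fixed acid-dissociation exponent (not fitted).
    fit_phi0
        If True (default) the formal potential floats; otherwise ``phi0``
        must be supplied (e.g. the low-pH plateau value).
    invert
        Report K_D in the water-favouring orientation 1/K_D instead of the
        organic-favouring one used internally (see module docstring).

    Returns
    -------
    (PartitionModel, diagnostics)
        ``diagnostics`` holds ``rms`` (V), ``n``, ``log10_KD``, and a
        ``note`` on data coverage.
    """
    arr = np.asarray(list(data), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be (pH, half_wave_potential) pairs")
    if arr.shape[0] < 5:
        raise ValueError(f"need at least 5 points, got {arr.shape[0]}")
    pH, y = arr[:, 0], arr[:, 1]
    if not fit_phi0 and phi0 is None:
        raise ValueError("phi0 must be supplied when fit_phi0 is False")

    note = ""
    if np.all(pH < pKa - 2):
        note = (
            "all points lie more than 2 pH units below pKa; the rising "
            "branch is unsampled and K_D is weakly constrained"
        )
        warnings.warn(note, stacklevel=2)
    if fit_phi0 and float(np.ptp(y)) < 1e-6:
        raise ValueError(
            "unidentifiable fit: half-wave potentials are flat, so phi0 "
            "and K_D cannot both be determined"
        )

    def sse(log10_kd: float) -> float:
        shift = _halfwave_shift(pH, pKa, 10.0**log10_kd, z, T)
        p0 = float(np.mean(y - shift)) if fit_phi0 else phi0
        resid = y - (p0 + shift)
        return float(resid @ resid)

    grid = np.arange(-2.0, 6.0 + 1e-9, 0.02)
    best = grid[int(np.argmin([sse(g) for g in grid]))]
    res = minimize_scalar(
        sse, bounds=(best - 0.05, best + 0.05), method="bounded",
        options={"xatol": 1e-10},
    )
    log10_kd = float(res.x) if res.fun <= sse(best) else float(best)

    kd = 10.0**log10_kd
    shift = _halfwave_shift(pH, pKa, kd, z, T)
    phi0_hat = float(np.mean(y - shift)) if fit_phi0 else float(phi0)
    resid = y - (phi0_hat + shift)
    rms = float(np.sqrt(np.mean(resid**2)))

    model = PartitionModel(phi0=phi0_hat, pKa=pKa, K_D=kd, z=z, T=T)
    diagnostics = {
        "rms": rms,
        "n": int(arr.shape[0]),
        "log10_KD": log10_kd,
        "K_D_reported": (1.0 / kd) if invert else kd,
        "orientation": "aq/org" if invert else "org/aq",
        "fit_phi0": bool(fit_phi0),
        "note": note or "ok",
    }
    return model, diagnostics


# ---------------------------------------------------------------------------
# Lipophilicity and Gibbs energy of transfer
# ---------------------------------------------------------------------------


def logp_from_phi(phi_formal: float, z: int = 1, T: float = T_DEFAULT) -> float:
    """Formal partition coefficient of the ion from its transfer potential.

    logP' = -phi * z * F / (2.303 * R * T).  For a cation a more positive
    transfer potential means greater hydrophilicity (more negative logP').
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -phi_formal * z * F / (np.log(10.0) * R * T)


def gibbs_from_phi(phi_formal: float, z: int = 1) -> float:
    """Formal Gibbs energy of ion transfer (aqueous -> organic), kJ mol^-1.

    dG' = z * F * phi ; positive for a hydrophilic ion that resists
    transfer into the organic phase.
    """
    return z * F * phi_formal / 1000.0


@dataclass
class PhysChemConstants:
    """Bundle of derived physicochemical constants for one analyte.

    The logP/Gibbs identity dG = -2.303*R*T*logP/1000 is enforced on
    construction (the two are the same measurement on different scales).
    """

    phi_formal: float
    logP_water_org: float
    deltaG_transfer_kJ_mol: float
    D_fwd: float | None = None
    D_bwd: float | None = None
    K_D: float | None = None
    T: float = T_DEFAULT
    z: int = 1

    def __post_init__(self) -> None:
        expected = -np.log(10.0) * R * self.T * self.logP_water_org / 1000.0
        if not np.isclose(self.deltaG_transfer_kJ_mol, expected, rtol=1e-9, atol=1e-12):
            raise ValueError(
                "inconsistent constants: deltaG must equal "
                "-2.303*R*T*logP/1000"
            )

    @classmethod
    def from_phi(
        cls,
        phi_formal: float,
        z: int = 1,
        T: float = T_DEFAULT,
        D_fwd: float | None = None,
        D_bwd: float | None = None,
        K_D: float | None = None,
    ) -> "PhysChemConstants":
        return cls(
            phi_formal=phi_formal,
            logP_water_org=logp_from_phi(phi_formal, z, T),
            deltaG_transfer_kJ_mol=gibbs_from_phi(phi_formal, z),
            D_fwd=D_fwd,
            D_bwd=D_bwd,
            K_D=K_D,
            T=T,
            z=z,
        )

    def as_dict(self) -> dict:
        return {
            "phi_formal_V": self.phi_formal,
            "logP_water_org": self.logP_water_org,
            "deltaG_transfer_kJ_mol": self.deltaG_transfer_kJ_mol,
            "D_fwd_cm2_s": self.D_fwd,
            "D_bwd_cm2_s": self.D_bwd,
            "K_D": self.K_D,
            "T_K": self.T,
            "z": self.z,
        }
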