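"""ITC analysis and Spolar–Record thermodynamic dissection.

Single-site binding fits of injection heats with per-injection dilution
bookkeeping, the free-energy/entropy identities ΔG = RT·ln(K_D) and
−TΔS = ΔG − ΔH, the heat-capacity change ΔCp as the slope of ΔH(T),
and the Spolar–Record estimate of the number of residues ℜ that fold
upon binding:

    ΔS_HE   = c_HE · ΔCp · ln(T / T_s)          (hydration entropy)
    ΔS_conf = ΔS_assoc − ΔS_HE − ΔS_rt          (conformational entropy)
    ℜ       = ΔS_conf / ΔS_res

with defaults c_HE = 1.35 (hydration-to-ΔCp proportionality),
T_s = 386 K (the temperature at which the hydration entropy of
hydrophobic burial vanishes), ΔS_rt = −50 cal mol⁻¹ K⁻¹
(rotational–translational entropy loss of bimolecular association) and
ΔS_res = −5.6 cal mol⁻¹ K⁻¹ residue⁻¹ (mean backbone conformational
entropy per folding residue).  All constants are overridable; a
coupled-folding reaction with ΔCp < 0 gives ℜ > 0.

Units follow calorimetric convention: ΔG/ΔH/−TΔS in kcal/mol, ΔCp and
entropies in cal mol⁻¹ K⁻¹, K_D in molar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy import stats

from .simkit import itc_injection_heats

__all__ = [
    "R_KCAL", "ThermoParams", "SpolarRecordConstants",
    "fit_single_site", "free_energy", "entropy_term",
    "heat_capacity", "residues_folded",
]

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3


@dataclass
class ThermoParams:
    """Thermodynamic signature of one binding reaction."""

    K_D: float                  # M
    dG: float                   # kcal/mol
    dH: float                   # kcal/mol
    minus_TdS: float            # kcal/mol
    temperature: float          # K
    dCp: float = math.nan       # cal/mol/K
    R_fold: float = math.nan    # residues
    uncertainties: dict | None = None

    def __post_init__(self):
        if abs(self.dG - (self.dH + self.minus_TdS)) > 1e-6:
            raise ValueError("dG must equal dH + minus_TdS")


@dataclass(frozen=True)
class SpolarRecordConstants:
    """Constants of the entropy dissection (see module docstring)."""

    hydration_coeff: float = 1.35
    dS_rt: float = -50.0          # cal/mol/K
    dS_per_residue: float = -5.6  # cal/mol/K/residue
    T_s: float = 386.0            # K


# ---------------------------------------------------------------------------
# Single-site fit
# ---------------------------------------------------------------------------

@dataclass
class SingleSiteFit:
    K_D: float
    dH: float                    # kcal/mol
    n: float
    K_D_err: float
    dH_err: float
    n_err: float
    c_value: float               # n * cell_conc / K_D
    rms_residual: float          # µcal
    flags: list


def fit_single_site(titration, cell_conc: float, syringe_conc: float,
                    cell_volume: float = 200.0, temperature: float = 298.15,
                    fit_n: bool = True) -> SingleSiteFit:
    """Fit a 1:1 binding isotherm to an injection-heat table.

    ``titration`` is a DataFrame with columns ``volume_uL`` and
    ``heat_ucal`` (as written by the simulator).  The model is the
    exact single-site isotherm with displacement dilution bookkeeping,
    identical to the generative model, so noiseless data round-trips to
    machine precision.  K_D is searched in log space.
    """
    df = pd.DataFrame(titration)
    if len(df) < 8:
        raise ValueError("need at least 8 injections")
    if cell_conc <= 0 or syringe_conc <= 0:
        raise ValueError("concentrations must be > 0")
    vols = df["volume_uL"].to_numpy(float)
    q_obs = df["heat_ucal"].to_numpy(float)

    flags = []
    scale = float(np.max(np.abs(q_obs)))
    if scale == 0.0:
        flags.append("all heats zero: dH = 0, K_D unidentifiable")
        return SingleSiteFit(K_D=math.nan, dH=0.0, n=1.0,
                             K_D_err=math.inf, dH_err=0.0, n_err=math.inf,
                             c_value=math.nan, rms_residual=0.0, flags=flags)

    def model(theta):
        logKd, dH, n = theta
        return itc_injection_heats(10 ** logKd, dH, n, cell_conc,
                                   syringe_conc, vols, cell_volume)

    def resid(theta):
        return model(theta) - q_obs

    dH0 = np.sum(q_obs) / (syringe_conc * np.sum(vols) * 1e-6 * 1e9) \
        if syringe_conc > 0 else -10.0
    x0 = np.array([math.log10(cell_conc) - 2.0, dH0, 1.0])
    lo = [-15.0, -500.0, 0.2 if fit_n else 1.0 - 1e-12]
    hi = [0.0, 500.0, 5.0 if fit_n else 1.0 + 1e-12]
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    logKd, dH, n = sol.x
    K_D = 10 ** logKd

    dof = max(len(q_obs) - 3, 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
        perr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        perr = np.full(3, np.inf)
    K_D_err = K_D * math.log(10) * perr[0]

    c_value = n * cell_conc / K_D
    if not (1.0 <= c_value <= 1e4):
        flags.append(f"c-value {c_value:.3g} outside [1, 1e4]: "
                     "K_D poorly determined by the isotherm shape")
        warnings.warn(flags[-1], stacklevel=2)
    return SingleSiteFit(K_D=float(K_D), dH=float(dH), n=float(n),
                         K_D_err=float(K_D_err), dH_err=float(perr[1]),
                         n_err=float(perr[2]), c_value=float(c_value),
                         rms_residual=float(np.sqrt(np.mean(sol.fun ** 2))),
                         flags=flags)


# ---------------------------------------------------------------------------
# State-function bookkeeping
# ---------------------------------------------------------------------------

def free_energy(K_D: float, T: float) -> float:
    """ΔG = R·T·ln(K_D), kcal/mol (negative for K_D < 1 M)."""
    if K_D <= 0 or T <= 0:
        raise ValueError("K_D and T must be > 0")
    return R_KCAL * T * math.log(K_D)


def entropy_term(dG: float, dH: float) -> float:
    """−TΔS = ΔG − ΔH, kcal/mol."""
    return dG - dH


def heat_capacity(dH_series) -> tuple:
    """ΔCp (cal mol⁻¹ K⁻¹) as the OLS slope of ΔH (kcal/mol) over T (K).

    ``dH_series`` is an iterable of (T, dH) pairs; returns
    (dCp, dCp_stderr).  Requires at least 3 temperatures.
    """
    pts = np.asarray(list(dH_series), float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (T, dH) points")
    T, dH = pts[:, 0], pts[:, 1]
    res = stats.linregress(T, dH)
    return res.slope * 1e3, res.stderr * 1e3


# ---------------------------------------------------------------------------
# Spolar–Record residues folded
# ---------------------------------------------------------------------------

@dataclass
class ResiduesFoldedResult:
    R_fold: float
    dS_assoc: float      # cal/mol/K at evaluation temperature
    dS_HE: float         # hydration-entropy term
    dS_conf: float       # conformational term
    evaluation_T: float  # K
    flags: list


def residues_folded(dCp: float, minus_TdS: float, T: float,
                    constants: SpolarRecordConstants = SpolarRecordConstants(),
                    evaluate_at: str = "measurement") -> ResiduesFoldedResult:
    """Number of residues that fold upon binding (Spolar–Record).

    ``minus_TdS`` is the calorimetric −TΔS (kcal/mol) at temperature
    ``T``; ``dCp`` in cal mol⁻¹ K⁻¹ (negative for folding-coupled
    binding).  ``evaluate_at="measurement"`` (default) dissects the
    association entropy at T; ``evaluate_at="Ts"`` first extrapolates
    ΔS_assoc to T_s with ΔCp, where the hydration term vanishes by
    construction.  All intermediate terms are returned for audit.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    flags = []
    if dCp >= 0:
        flags.append("dCp >= 0: binding is not folding-coupled; "
                     "the hydration dissection does not apply")
    dS_assoc_T = -minus_TdS * 1e3 / T        # cal/mol/K
    if evaluate_at == "measurement":
        T_eval = T
        dS_assoc = dS_assoc_T
        dS_HE = constants.hydration_coeff * dCp * math.log(T / constants.T_s)
    elif evaluate_at == "Ts":
        T_eval = constants.T_s
        dS_assoc = dS_assoc_T + dCp * math.log(constants.T_s / T)
        dS_HE = 0.0
    else:
        raise ValueError("evaluate_at must be 'measurement' or 'Ts'")
    dS_conf = dS_assoc - dS_HE - constants.dS_rt
    R_fold = dS_conf / constants.dS_per_residue
    if R_fold < 0:
        flags.append(
            f"unphysical R_fold < 0 (dS_assoc={dS_assoc:.1f}, "
            f"dS_HE={dS_HE:.1f}, dS_conf={dS_conf:.1f} cal/mol/K)")
    return ResiduesFoldedResult(R_fold=float(R_fold), dS_assoc=float(dS_assoc),
                                dS_HE=float(dS_HE), dS_conf=float(dS_conf),
                                evaluation_T=float(T_eval), flags=flags)


def thermo_params(K_D: float, dH: float, T: float, dCp: float = math.nan,
                  constants: SpolarRecordConstants = SpolarRecordConstants()
                  ) -> ThermoParams:
    """Assemble a full :class:`ThermoParams` from K_D, ΔH (and ΔCp)."""
    dG = free_energy(K_D, T)
    mTdS = entropy_term(dG, dH)
    R_fold = math.nan
    if not math.isnan(dCp):
        R_fold = residues_folded(dCp, mTdS, T, constants).R_fold
    return ThermoParams(K_D=K_D, dG=dG, dH=dH, minus_TdS=mTdS,
                        temperature=T, dCp=dCp, R_fold=R_fold)
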