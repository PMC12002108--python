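"""Isothermal titration calorimetry: thermodynamic algebra and proton linkage.

Binding of Zn(II) to a designed peptide at constant pH exchanges protons
with the buffer, so the calorimetrically observed enthalpy depends
linearly on the buffer's ionization enthalpy:

    dH_obs = dH_bind + n_H+ * dH_ion

Titrating in several buffers of different dH_ion and fitting a straight
line recovers the buffer-corrected binding enthalpy (intercept) and the
signed number of exchanged protons (slope; negative when protons are
released on complex formation).

The equilibrium algebra uses dG_bind = RT ln K_D = -RT ln K_A, which is
negative for sub-molar dissociation constants (a 220 nM K_D at 298.15 K
gives -9.1 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "R_KCAL",
    "STANDARD_TEMPERATURE",
    "BUFFER_IONIZATION_ENTHALPY_KCAL",
    "BindingThermo",
    "BufferTitration",
    "ProtonLinkageFit",
    "dg_from_kd",
    "kd_from_dg",
    "ka_from_kd",
    "tds_from",
    "proton_linkage_fit",
    "titrations_from_csv",
]

#: Gas constant, kcal / (mol K).
R_KCAL = 1.98720425e-3

#: Default experiment temperature, K.
STANDARD_TEMPERATURE = 298.15

#: Buffer ionization enthalpies at 298.15 K, kcal/mol.
#: Literature values (Goldberg, Kishore & Lennen, J. Phys. Chem. Ref. Data
#: 31, 231 (2002)), shipped as an editable default table — measure or
#: override for your own buffer lots.
BUFFER_IONIZATION_ENTHALPY_KCAL: dict[str, float] = {
    "ACES": 7.27,
    "HEPES": 4.88,
    "PIPES": 2.68,
    "cacodylate": -0.72,
}


@dataclass
class BufferTitration:
    """Observed binding enthalpy for one buffer."""

    buffer_name: str
    dH_ion: float  # buffer ionization enthalpy, kcal/mol
    dH_obs: float  # observed binding enthalpy in that buffer, kcal/mol

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dH_ion) and math.isfinite(self.dH_obs)):
            raise ValueError("titration enthalpies must be finite")


@dataclass
class BindingThermo:
    """Equilibrium thermodynamics of one metal-peptide interaction.

    Sign conventions follow the usual ITC reporting: ``dG = dH + minus_TdS``
    and ``n_Hplus`` is negative when protons are released on binding.
    """

    T: float = STANDARD_TEMPERATURE
    K_D: float | None = None  # mol/L
    dG: float | None = None  # kcal/mol
    dH: float | None = None  # kcal/mol
    minus_TdS: float | None = None  # kcal/mol
    stoichiometry: float | None = None
    n_Hplus: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.K_D is not None and self.K_D <= 0:
            raise ValueError("K_D must be positive")
        if self.K_D is not None and self.dG is None:
            self.dG = dg_from_kd(self.K_D, self.T)
        if self.dG is not None and self.dH is not None and self.minus_TdS is None:
            self.minus_TdS = tds_from(self.dG, self.dH)
        self.validate()

    @property
    def K_A(self) -> float | None:
        return None if self.K_D is None else 1.0 / self.K_D

    def validate(self) -> None:
        if self.K_D is not None:
            if abs(self.K_A * self.K_D - 1.0) > 1e-9:
                raise ValueError("K_A * K_D must equal 1")
            if self.dG is not None and abs(self.dG - dg_from_kd(self.K_D, self.T)) > 1e-6:
                raise ValueError("dG inconsistent with K_D at this temperature")
        if None not in (self.dG, self.dH, self.minus_TdS):
            if abs(self.dG - (self.dH + self.minus_TdS)) > 1e-9:
                raise ValueError("dG must equal dH - T dS")


def dg_from_kd(K_D: float, T: float = STANDARD_TEMPERATURE) -> float:
    """Gibbs energy of binding (kcal/mol) from the dissociation constant.

    dG_bind = RT ln K_D, negative for sub-molar K_D.
    """
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * T * math.log(K_D)


def kd_from_dg(dG: float, T: float = STANDARD_TEMPERATURE) -> float:
    """Dissociation constant (mol/L) from the Gibbs energy of binding."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dG / (R_KCAL * T))


def ka_from_kd(K_D: float) -> float:
    """Association constant (1/M) from the dissociation constant."""
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    return 1.0 / K_D


def tds_from(dG: float, dH: float) -> float:
    """Entropic term -T dS (kcal/mol) from dG and dH: -T dS = dG - dH."""
    return dG - dH


@dataclass(frozen=True)
class ProtonLinkageFit:
    """OLS fit of dH_obs on dH_ion across buffers."""

    dH_bind: float  # intercept: buffer-corrected binding enthalpy, kcal/mol
    n_Hplus: float  # slope: signed proton count (negative = released)
    dH_bind_se: float
    n_Hplus_se: float
    residuals: tuple[float, ...]
    n_obs: int


def proton_linkage_fit(titrations: Iterable[BufferTitration]) -> ProtonLinkageFit:
    """Fit the proton-linkage line over per-buffer titrations.

    Ordinary least squares of dH_obs on dH_ion; the slope is the signed
    proton count n_H+ and the intercept the buffer-corrected binding
    enthalpy.  Needs at least two titrations at distinct dH_ion.
    """
    data = list(titrations)
    if len(data) < 2:
        raise ValueError("need at least two buffer titrations")
    x = np.array([t.dH_ion for t in data])
    y = np.array([t.dH_obs for t in data])
    if np.ptp(x) < 1e-12:
        raise ValueError(
            "all buffer ionization enthalpies identical: slope is unidentifiable"
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    se_intercept, se_slope = model.bse
    return ProtonLinkageFit(
        dH_bind=float(intercept),
        n_Hplus=float(slope),
        dH_bind_se=float(se_intercept),
        n_Hplus_se=float(se_slope),
        residuals=tuple(float(r) for r in model.resid),
        n_obs=len(data),
    )


def titrations_from_csv(text_or_path, from_path: bool = False) -> list[BufferTitration]:
    """Read titrations from CSV with columns buffer_name, dH_ion, dH_obs.

    A missing/empty dH_ion is filled from the shipped literature table
    when the buffer name is known.
    """
    import io

    df = pd.read_csv(text_or_path if from_path else io.StringIO(text_or_path))
    required = {"buffer_name", "dH_obs"}
    if not required <= set(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required | {'dH_ion'})}")
    out = []
    for _, row in df.iterrows():
        dh_ion = row.get("dH_ion")
        if dh_ion is None or (isinstance(dh_ion, float) and math.isnan(dh_ion)):
            try:
                dh_ion = BUFFER_IONIZATION_ENTHALPY_KCAL[str(row["buffer_name"])]
            except KeyError:
                raise ValueError(
                    f"no dH_ion given and buffer {row['buffer_name']!r} not in the "
                    "default ionization-enthalpy table"
                ) from None
        out.append(
            BufferTitration(
                buffer_name=str(row["buffer_name"]),
                dH_ion=float(dh_ion),
                dH_obs=float(row["dH_obs"]),
            )
        )
    return out
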