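"""Cox-type shear-lag link between tissue strain and fibril strain.

A stiff fibril of aspect ratio xi_F embedded at volume fraction phi_F in a
compliant matrix of shear modulus G_M picks up only a fraction of the
surrounding tissue strain: eps_F = A_F(kappa) * eps_T with

    A_F(kappa) = 1 - tanh(kappa/2) / (kappa/2),
    kappa      = sqrt(G_M / E_F) * xi_F / sqrt(ln(1 / phi_F)),

so a measured strain-concentration factor A_F inverts to kappa and, given
xi_F and phi_F, to the matrix-to-fibril modulus ratio G_M / E_F.  The
logarithm is natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ShearLagParams",
    "strain_concentration",
    "invert_concentration",
    "modulus_ratio",
    "fit_AF",
    "AFFit",
]

#: default fibril aspect ratio and volume fraction (literature values)
XI_F_DEFAULT = 100.0
PHI_F_DEFAULT = 0.20


def strain_concentration(kappa: float) -> float:
    """Strain-concentration factor A_F = 1 - tanh(kappa/2)/(kappa/2).

    Strictly increasing from 0 (kappa -> 0, behaving as kappa^2/12) to 1
    (rigid coupling, kappa -> inf).
    """
    k = float(kappa)
    if k <= 0:
        raise ValueError("kappa must be > 0")
    x = k / 2.0
    if x < 1e-4:
        # series: tanh(x)/x = 1 - x^2/3 + 2 x^4/15 - ...
        return x * x / 3.0 - 2.0 * x**4 / 15.0
    return 1.0 - math.tanh(x) / x


def invert_concentration(AF: float, tol: float = 1e-12) -> float:
    """Unique kappa with strain_concentration(kappa) == AF, by bracketed root find.

    A_F is strictly increasing in kappa, so the root on [1e-6, 1e3] is
    unique; AF outside (0, 1) has no solution.
    """
    af = float(AF)
    if not 0.0 < af < 1.0:
        raise ValueError("AF must lie strictly between 0 and 1")
    lo, hi = 1e-6, 1e3
    if af <= strain_concentration(lo):
        return lo
    if af >= strain_concentration(hi):
        return hi
    return float(brentq(lambda k: strain_concentration(k) - af, lo, hi, xtol=tol))


def modulus_ratio(kappa: float, xi_F: float = XI_F_DEFAULT,
                  phi_F: float = PHI_F_DEFAULT) -> float:
    """Matrix-to-fibril modulus ratio G_M / E_F = kappa^2 ln(1/phi_F) / xi_F^2."""
    if kappa <= 0 or xi_F <= 0:
        raise ValueError("kappa and xi_F must be > 0")
    if not 0.0 < phi_F < 1.0:
        raise ValueError("phi_F must lie strictly between 0 and 1")
    return kappa**2 * math.log(1.0 / phi_F) / xi_F**2


@dataclass(frozen=True)
class ShearLagParams:
    """Consistent bundle of shear-lag quantities.

    Constructing from AF (or kappa) fills in the rest; ``EF_GPa`` optionally
    converts the modulus ratio to an absolute matrix shear modulus.
    """

    AF: float
    kappa: float
    xi_F: float = XI_F_DEFAULT
    phi_F: float = PHI_F_DEFAULT
    EF_GPa: float | None = None

    def __post_init__(self) -> None:
        if abs(self.AF - strain_concentration(self.kappa)) > 1e-10:
            raise ValueError("AF and kappa are inconsistent with the shear-lag map")

    @classmethod
    def from_AF(cls, AF: float, xi_F: float = XI_F_DEFAULT,
                phi_F: float = PHI_F_DEFAULT, EF_GPa: float | None = None):
        kappa = invert_concentration(AF)
        return cls(AF=strain_concentration(kappa), kappa=kappa, xi_F=xi_F,
                   phi_F=phi_F, EF_GPa=EF_GPa)

    @property
    def GM_over_EF(self) -> float:
        return modulus_ratio(self.kappa, self.xi_F, self.phi_F)

    @property
    def GM_GPa(self) -> float | None:
        return None if self.EF_GPa is None else self.GM_over_EF * self.EF_GPa


@dataclass
class AFFit:
    """Through-origin regression of fibril strain on tissue strain."""

    AF: float
    stderr: float
    per_sample: dict
    n_pairs: int


def fit_AF(pairs) -> AFFit:
    """Estimate A_F from matched (tissue strain, fibril strain) pairs.

    ``pairs`` is a DataFrame-like with columns ``eps_T_pct``, ``eps_F_pct``
    and optionally ``sample``.  The proportional model eps_F = A_F eps_T
    has no intercept, so the estimate is the through-origin least-squares
    slope per sample; the reported A_F is the mean across samples with its
    standard error (s.e.m.; zero for a single sample).
    """
    import pandas as pd

    df = pd.DataFrame(pairs)
    df = df.dropna(subset=["eps_T_pct", "eps_F_pct"])
    if len(df) < 3:
        raise ValueError("need at least 3 strain pairs")
    if "sample" not in df.columns:
        df = df.assign(sample=0)
    slopes = {}
    for name, g in df.groupby("sample"):
        sxx = float(np.sum(g["eps_T_pct"] ** 2))
        if sxx < 1e-12:
            continue
        slopes[name] = float(np.sum(g["eps_T_pct"] * g["eps_F_pct"]) / sxx)
    if not slopes:
        raise ValueError("no tissue strain signal: all eps_T are ~0")
    vals = np.array(list(slopes.values()))
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return AFFit(AF=float(np.mean(vals)), stderr=se, per_sample=slopes,
                 n_pairs=len(df))
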