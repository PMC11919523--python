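"""Large-deflection equilibrium of a curved bilayer beam and layer-modulus inversion.

The cuticle is idealised as a planar, extensible, unshearable rod with an
initially circular centreline (radius ``R``, central angle ``alpha``) and a
rectangular bilayer cross-section: a stiff outer exocuticle of thickness
``t1`` and Young's modulus ``E1`` on a compliant inner endocuticle of
thickness ``t2`` and modulus ``E2 = eta * E1``.  The ends are pinned and a
horizontal end displacement (chord shortening in compression, lengthening in
tension) is prescribed; the internal force is then constant along the rod.

Nondimensionalisation: lengths by the arc length ``L = R * alpha``, forces by
``E1 * b * h`` and moments by ``E1 * b * h * L``.  With that scaling the
boundary-value problem depends only on the arc geometry and the modulus ratio
``eta``; the physical load is recovered as ``H0 = E1 * b * h * H0_bar``, which
is what makes the joint ``(E1, eta)`` least-squares fit separable in ``E1``.

Sign conventions: the half-arc runs from the apex (``S_bar = 0``, tangent
parallel to the chord) to a pinned end (``S_bar = 1/2``); the tangent angle
``theta`` grows from 0 to ``alpha/2 + theta0``; compressive axial force is
negative, so ``H0 < 0`` in compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import minimize_scalar

__all__ = [
    "ArcGeometry",
    "SectionProperties",
    "MaterialParams",
    "BeamSolution",
    "ModuliFit",
    "section_properties",
    "integrate_equilibrium",
    "shoot",
    "tissue_strain_field",
    "linear_chord_compliance",
    "fit_moduli",
]

#: conversion factor: (GPa * mm^2) -> N
_GPA_MM2_TO_N = 1000.0


class BeamError(RuntimeError):
    """Solver failure (integration or shooting did not converge)."""


@dataclass(frozen=True)
class ArcGeometry:
    """Undeformed circular-arc bilayer specimen.

    ``t1`` is the outer (exocuticle) layer, measured from the convex surface;
    ``t2`` the inner (endocuticle) layer.  ``t1 + t2`` must equal ``h``.
    """

    R_mm: float
    alpha_rad: float
    b_mm: float
    h_mm: float
    t1_mm: float
    t2_mm: float

    def __post_init__(self) -> None:
        for name in ("R_mm", "alpha_rad", "b_mm", "h_mm", "t1_mm", "t2_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ArcGeometry.{name} must be > 0")
        if abs(self.t1_mm + self.t2_mm - self.h_mm) > 1e-9:
            raise ValueError("layer thicknesses must satisfy t1 + t2 == h")

    @property
    def L_mm(self) -> float:
        """Arc length ``R * alpha``."""
        return self.R_mm * self.alpha_rad

    @property
    def chord_mm(self) -> float:
        """Distance between the pinned ends, ``2 R sin(alpha/2)``."""
        return 2.0 * self.R_mm * math.sin(self.alpha_rad / 2.0)


@dataclass(frozen=True)
class SectionProperties:
    """Dimensionless stiffness of the bilayer cross-section (scaled by E1)."""

    z_n_mm: float   # neutral-axis depth from the outer surface
    EA_bar: float   # (t1 + eta t2) / h
    EI_bar: float   # E-weighted second moment / (h L^2)
    eta: float
    h_mm: float
    L_mm: float


@dataclass(frozen=True)
class MaterialParams:
    """Layer moduli; ``eta = E2 / E1``."""

    E1_GPa: float
    eta: float

    def __post_init__(self) -> None:
        if not self.E1_GPa > 0:
            raise ValueError("E1_GPa must be > 0")
        if not 0 < self.eta <= 1.5:
            raise ValueError("eta must lie in (0, 1.5]")

    @property
    def E2_GPa(self) -> float:
        return self.eta * self.E1_GPa


def section_properties(arc: ArcGeometry, eta: float) -> SectionProperties:
    """Modulus-weighted centroid and dimensionless axial/bending stiffness.

    z_n = [t1^2/2 + eta t2 (t1 + t2/2)] / (t1 + eta t2), measured from the
    outer (exocuticle) surface; EI_bar integrates (E(z)/E1)(z - z_n)^2 over
    the thickness and is scaled by h L^2.
    """
    if not eta > 0:
        raise ValueError("eta must be > 0")
    t1, t2, h, L = arc.t1_mm, arc.t2_mm, arc.h_mm, arc.L_mm
    denom = t1 + eta * t2
    z_n = (t1 * t1 / 2.0 + eta * t2 * (t1 + t2 / 2.0)) / denom
    ea_bar = denom / h
    i_exo = ((t1 - z_n) ** 3 + z_n**3) / 3.0
    i_endo = eta * ((h - z_n) ** 3 - (t1 - z_n) ** 3) / 3.0
    ei_bar = (i_exo + i_endo) / (h * L * L)
    return SectionProperties(z_n, ea_bar, ei_bar, eta, h, L)


@dataclass
class BeamSolution:
    """Equilibrium state of the half-arc in nondimensional variables.

    Fields are sampled on a uniform grid ``s_bar`` in [0, 1/2].  ``H_bar`` is
    the (constant) horizontal component of the internal force; end quantities
    follow the local tangent/normal decomposition at the pinned end.
    """

    arc: ArcGeometry
    section: SectionProperties
    H_bar: float
    V_bar: float
    M_apex_bar: float
    s_bar: np.ndarray
    theta: np.ndarray
    x_bar: np.ndarray
    z_bar: np.ndarray
    M_bar: np.ndarray
    N_bar: np.ndarray
    Q_bar: np.ndarray
    eps_axis: np.ndarray
    delta_mm: float = field(default=0.0)

    @property
    def theta_end(self) -> float:
        return float(self.theta[-1])

    @property
    def theta0(self) -> float:
        """End-rotation change from the undeformed value alpha/2."""
        return self.theta_end - self.arc.alpha_rad / 2.0

    @property
    def N0_bar(self) -> float:
        return float(self.N_bar[-1])

    @property
    def Q0_bar(self) -> float:
        return float(self.Q_bar[-1])

    @property
    def H0_bar(self) -> float:
        """Horizontal end force reconstructed from the end decomposition.

        H0_bar = N0_bar cos(alpha/2 + theta0) - Q0_bar sin(alpha/2 + theta0);
        identical to the applied ``H_bar`` for a converged symmetric solution.
        """
        a = self.arc.alpha_rad / 2.0 + self.theta0
        return self.N0_bar * math.cos(a) - self.Q0_bar * math.sin(a)

    def physical_load_N(self, E1_GPa: float) -> float:
        """Dimensional horizontal load ``H0 = E1 b h H0_bar`` in newtons."""
        return E1_GPa * self.arc.b_mm * self.arc.h_mm * self.H0_bar * _GPA_MM2_TO_N


def _rhs_factory(alpha: float, section: SectionProperties, H: float, V: float):
    ea, ei = section.EA_bar, section.EI_bar

    def rhs(_s, y):
        theta = y[2]
        ct, st = math.cos(theta), math.sin(theta)
        n = H * ct + V * st
        q = -H * st + V * ct
        eps = n / ea
        return (
            (1.0 + eps) * ct,           # x_bar'
            (1.0 + eps) * st,           # z_bar'
            alpha + y[3] / ei,          # theta'
            -(1.0 + eps) * q,           # M_bar'
        )

    return rhs


def integrate_equilibrium(
    arc: ArcGeometry,
    section: SectionProperties,
    end_force: tuple[float, float],
    M_apex_bar: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_samples: int = 101,
) -> BeamSolution:
    """Integrate the half-arc equilibrium ODEs from apex to end.

    Apex conditions: x_bar = z_bar = 0, theta = 0, M_bar = M_apex_bar; the
    internal force (H_bar, V_bar) is constant because there is no distributed
    load.  Returns the candidate solution without imposing the end conditions
    (those are the shooting residuals).
    """
    H, V = end_force
    if not all(map(math.isfinite, (H, V, M_apex_bar))):
        raise ValueError("end force and apex moment must be finite")
    rhs = _rhs_factory(arc.alpha_rad, section, H, V)
    sol = solve_ivp(
        rhs,
        (0.0, 0.5),
        (0.0, 0.0, 0.0, M_apex_bar),
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise BeamError(f"equilibrium integration failed: {sol.message}")
    s = np.linspace(0.0, 0.5, n_samples)
    x, z, theta, m = sol.sol(s)
    n = H * np.cos(theta) + V * np.sin(theta)
    q = -H * np.sin(theta) + V * np.cos(theta)
    return BeamSolution(
        arc=arc,
        section=section,
        H_bar=H,
        V_bar=V,
        M_apex_bar=M_apex_bar,
        s_bar=s,
        theta=theta,
        x_bar=x,
        z_bar=z,
        M_bar=m,
        N_bar=n,
        Q_bar=q,
        eps_axis=n / section.EA_bar,
    )


def linear_chord_compliance(arc: ArcGeometry, section: SectionProperties) -> float:
    """Chord compliance of the pinned arch by the unit-load (virtual work) method.

    Small-displacement theory on the undeformed geometry: a unit pair of
    horizontal forces at the pins produces moment ``m = e(phi)`` (the rise of
    the arc above the chord) and axial force ``n = cos(phi)``.  Returns the
    dimensionless compliance ``C`` such that ``delta = C * H / (E1 * b)``
    with lengths in mm.  Serves as an independent check on the shooting
    solver in its linear limit.
    """
    R, a2 = arc.R_mm, arc.alpha_rad / 2.0
    ei = section.EI_bar * arc.h_mm * arc.L_mm**2   # EI / (E1 b), mm^3
    ea = section.EA_bar * arc.h_mm                 # EA / (E1 b), mm
    c = math.cos(a2)

    def integrand(phi):
        e = R * (math.cos(phi) - c)
        return e * e / ei + math.cos(phi) ** 2 / ea

    val, _ = quad(integrand, -a2, a2, epsabs=1e-12, epsrel=1e-12)
    return R * val


def shoot(
    arc: ArcGeometry,
    section: SectionProperties,
    delta_mm: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    tol: float = 1e-10,
    max_iter: int = 50,
    initial_guess: tuple[float, float] | None = None,
) -> BeamSolution:
    """Solve the pinned-arch boundary-value problem for a prescribed chord change.

    ``delta_mm`` is the signed change of the chord (negative = compression).
    Unknowns are the horizontal internal force ``H_bar`` and the apex moment
    ``M_apex_bar``; residuals enforce the half-chord position of the end and a
    moment-free pinned end.  Damped Newton iteration with a finite-difference
    Jacobian.
    """
    if abs(delta_mm) > 0.05 * arc.chord_mm:
        raise ValueError(
            "prescribed displacement exceeds 5% of the chord (outside the "
            "elastic regime this model targets)"
        )
    L = arc.L_mm
    target_x = (arc.chord_mm + delta_mm) / 2.0 / L

    def residuals(u):
        sol = integrate_equilibrium(
            arc, section, (u[0], 0.0), u[1], rtol=rtol, atol=atol, n_samples=2
        )
        return np.array([sol.x_bar[-1] - target_x, sol.M_bar[-1]])

    if initial_guess is None:
        # linear virtual-work estimate for H_bar; apex moment from m = H * rise
        c_lin = linear_chord_compliance(arc, section)
        h0 = delta_mm / (c_lin * arc.h_mm)
        rise = arc.R_mm * (1.0 - math.cos(arc.alpha_rad / 2.0))
        u = np.array([h0, -h0 * rise / L])
    else:
        u = np.array(initial_guess, dtype=float)

    r = residuals(u)
    scale = np.array([max(abs(u[0]), 1e-6), max(abs(u[1]), 1e-7)])
    for _ in range(max_iter):
        if np.linalg.norm(r) < tol:
            break
        jac = np.empty((2, 2))
        for j in range(2):
            du = np.zeros(2)
            du[j] = 1e-7 * scale[j]
            jac[:, j] = (residuals(u + du) - r) / du[j]
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError as exc:
            raise BeamError(f"singular shooting Jacobian at u={u}") from exc
        lam, norm0 = 1.0, np.linalg.norm(r)
        for _ in range(10):
            r_new = residuals(u + lam * step)
            if np.linalg.norm(r_new) < norm0:
                break
            lam *= 0.5
        u = u + lam * step
        r = r_new
        scale = np.maximum(np.abs(u), [1e-6, 1e-7])
    else:
        raise BeamError(
            f"shooting did not converge: residuals={r}, unknowns={u}"
        )

    sol = integrate_equilibrium(
        arc, section, (u[0], 0.0), u[1], rtol=rtol, atol=atol, n_samples=201
    )
    sol.delta_mm = delta_mm
    return sol


def tissue_strain_field(
    solution: BeamSolution,
    section: SectionProperties,
    Z_mm,
    S_mm=0.0,
) -> np.ndarray:
    """Tissue (cuticle-level) strain at depth ``Z`` and arc position ``S``, in %.

    ``Z`` is measured from the outer exocuticle surface toward the arc centre
    and ``S`` along the undeformed centreline from the apex.  The strain is
    the axial centreline strain plus the bending contribution
    ``(z_n - Z) * delta_kappa`` with the physical curvature change
    ``delta_kappa = M_bar / (EI_bar * L)``.
    """
    Z = np.asarray(Z_mm, dtype=float)
    S = np.asarray(S_mm, dtype=float)
    if np.any(Z < -1e-12) or np.any(Z > section.h_mm + 1e-12):
        raise ValueError("Z must lie within the thickness [0, h]")
    s_bar = np.abs(S) / section.L_mm
    eps = np.interp(s_bar, solution.s_bar, solution.eps_axis)
    m = np.interp(s_bar, solution.s_bar, solution.M_bar)
    dkappa = m / (section.EI_bar * section.L_mm)   # 1/mm
    return 100.0 * (eps + (section.z_n_mm - Z) * dkappa)


@dataclass
class ModuliFit:
    """Result of the joint (E1, eta) inversion from load-displacement steps."""

    params: MaterialParams
    objective: float
    residuals_N: np.ndarray
    predicted_N: np.ndarray
    eta_identifiable: bool
    E1_stderr_GPa: float
    eta_stderr: float
    n_steps: int


def _load_coefficients(arc: ArcGeometry, eta: float, deltas: np.ndarray) -> np.ndarray:
    """Model load per unit E1 (N per GPa) at each prescribed displacement."""
    section = section_properties(arc, eta)
    coeff = np.empty(len(deltas))
    guess = None
    for i, d in enumerate(deltas):
        sol = shoot(arc, section, float(d), initial_guess=guess)
        guess = (sol.H_bar, sol.M_apex_bar)
        coeff[i] = arc.b_mm * arc.h_mm * sol.H0_bar * _GPA_MM2_TO_N
    return coeff


def fit_moduli(
    load_steps,
    arc: ArcGeometry,
    *,
    eta_bounds: tuple[float, float] = (0.02, 1.0),
    eta_grid=(0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.65, 0.8, 1.0),
) -> ModuliFit:
    """Invert (E1, eta) from stepwise (displacement, load) pairs.

    Residuals are weighted by the inverse observed load (load-cell noise is
    predominantly multiplicative over the stepwise range, so relative errors
    are homoscedastic).  The model load is linear in E1 at fixed eta, so E1
    is profiled out analytically and the remaining 1-D objective in eta is
    minimised over a coarse multistart grid followed by bounded scalar
    refinement.  A flat profiled objective (all grid values within a
    negligible fraction of the weighted load scale) flags weak eta
    identifiability.
    """
    steps = np.asarray(load_steps, dtype=float).reshape(-1, 2)
    steps = steps[np.abs(steps[:, 0]) > 0]
    if len(steps) < 2:
        raise ValueError("need at least 2 load steps with nonzero displacement")
    deltas, loads = steps[:, 0], steps[:, 1]
    order = np.argsort(np.abs(deltas))
    deltas, loads = deltas[order], loads[order]
    w = np.where(np.abs(loads) > 1e-12, 1.0 / np.maximum(np.abs(loads), 1e-12), 1.0)

    cache: dict[float, tuple[float, float]] = {}

    def profiled_sse(eta: float) -> float:
        key = round(float(eta), 12)
        if key not in cache:
            coeff = _load_coefficients(arc, key, deltas)
            num = float((w * w * coeff) @ loads)
            den = float((w * coeff) @ (w * coeff))
            e1 = max(num / den, 1e-9) if den > 0 else 1e-9
            sse = float(np.sum((w * (e1 * coeff - loads)) ** 2))
            cache[key] = (sse, e1)
        return cache[key][0]

    grid = [g for g in eta_grid if eta_bounds[0] <= g <= eta_bounds[1]]
    sse_grid = [profiled_sse(g) for g in grid]
    i_best = int(np.argmin(sse_grid))
    lo = grid[i_best - 1] if i_best > 0 else eta_bounds[0]
    hi = grid[i_best + 1] if i_best < len(grid) - 1 else eta_bounds[1]
    res = minimize_scalar(
        profiled_sse, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-5},
    )
    eta_hat = float(res.x)
    sse, e1_hat = cache[round(eta_hat, 12)]

    load_scale = float(np.mean((w * loads) ** 2))
    flat = (max(sse_grid) - min(sse_grid)) < 1e-6 * load_scale * len(loads)

    coeff = _load_coefficients(arc, round(eta_hat, 12), deltas)
    predicted = e1_hat * coeff
    residuals = predicted - loads

    e1_se, eta_se = _fit_stderr(
        lambda e1, eta: float(
            np.sum((w * (e1 * _cached_coeff(arc, eta, deltas, cache) - loads)) ** 2)
        ),
        e1_hat,
        eta_hat,
        sse,
        len(loads),
    )
    params = MaterialParams(E1_GPa=e1_hat, eta=min(max(eta_hat, 1e-6), 1.5))
    return ModuliFit(
        params=params,
        objective=sse,
        residuals_N=residuals,
        predicted_N=predicted,
        eta_identifiable=not flat,
        E1_stderr_GPa=e1_se,
        eta_stderr=eta_se,
        n_steps=len(loads),
    )


_coeff_cache: dict = {}


def _cached_coeff(arc, eta, deltas, _state):
    key = (id(arc), round(float(eta), 12), deltas.tobytes())
    if key not in _coeff_cache:
        _coeff_cache[key] = _load_coefficients(arc, float(eta), deltas)
    return _coeff_cache[key]


def _fit_stderr(sse_fn, e1, eta, sse0, n) -> tuple[float, float]:
    """Asymptotic standard errors from the numerical Hessian of the SSE."""
    dof = max(n - 2, 1)
    sigma2 = sse0 / dof
    d1 = max(1e-4 * e1, 1e-6)
    d2 = 1e-3
    try:
        h11 = (sse_fn(e1 + d1, eta) - 2 * sse0 + sse_fn(e1 - d1, eta)) / d1**2
        h22 = (sse_fn(e1, eta + d2) - 2 * sse0 + sse_fn(e1, eta - d2)) / d2**2
        h12 = (
            sse_fn(e1 + d1, eta + d2)
            - sse_fn(e1 + d1, eta - d2)
            - sse_fn(e1 - d1, eta + d2)
            + sse_fn(e1 - d1, eta - d2)
        ) / (4 * d1 * d2)
        hess = np.array([[h11, h12], [h12, h22]]) / 2.0
        cov = sigma2 * np.linalg.inv(hess)
        return float(np.sqrt(max(cov[0, 0], 0.0))), float(np.sqrt(max(cov[1, 1], 0.0)))
    except (np.linalg.LinAlgError, ValueError):
        return float("nan"), float("nan")
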