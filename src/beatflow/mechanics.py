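"""Isotropic linear-elastic sheet with active contractile stress.

A flat cell layer obeying Hooke's law sigma = c1*eps + c2*I*Tr(eps)
carries an isotropic active stress sigma* inside a contractile core of
radius r0 and is optionally coupled to the substrate by an elastic drag
of spring constant k.  Radially symmetric solutions are closed-form:

* k = 0 (free sheet): u = b*r inside the core with
  b = -sigma*/(c1 + 2 c2), and the divergence-free u = a/r outside,
  matched by displacement continuity at r0.  The convergence
  C = -div(u) equals the constant 2*sigma*/(c1 + 2 c2) inside the core
  and vanishes identically outside.

* k > 0 (adhered sheet): the radial equation becomes the modified
  Bessel equation of order one in rho = r/lambda with decay length
  lambda = sqrt((c1 + c2)/k).  The inner solution is A*I1(rho), the
  outer B*K1(rho); the prefactors are fixed numerically by continuity
  of the displacement and of the total radial traction
  sigma_rr + sigma*_rr across r0.  Outside the core the convergence is
  negative (a divergent halo) and decays like sqrt(pi/(2 rho)) e^-rho.

For a spatially distributed contractility the displacement and its
convergence are linear responses: convolutions of sigma*(r') with a K1
kernel and with delta/(c1+c2) - K0/(2 pi lambda^2 (c1+c2)) respectively,
which reduce to the closed forms above for a uniform core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special
from scipy.signal import fftconvolve

from .errors import InputError

__all__ = [
    "SheetParams",
    "RadialSolution",
    "ContractilityField",
    "strain_polar",
    "hooke_stress",
    "solve_uniform_core",
    "response_kernel",
    "displacement_from_contractility",
    "convergence_from_contractility",
]


@dataclass(frozen=True)
class SheetParams:
    """Material and activity parameters of the contractile sheet.

    ``c1`` and ``c2`` are the Hooke moduli, ``k`` the substrate drag
    spring constant (0 for a free sheet), ``sigma_star`` the magnitude
    of the isotropic active stress, ``r0`` the core radius.
    """

    c1: float = 1.0
    c2: float = 1.0
    k: float = 0.0
    sigma_star: float = 1.0
    r0: float = 1.0

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise InputError("c1 must be positive")
        if self.c1 + 2 * self.c2 <= 0:
            raise InputError("c1 + 2*c2 must be positive")
        if self.c1 + self.c2 <= 0:
            raise InputError("c1 + c2 must be positive")
        if self.k < 0:
            raise InputError("substrate drag k must be nonnegative")
        if self.r0 <= 0:
            raise InputError("core radius r0 must be positive")

    @property
    def lam(self) -> float:
        """Decay length lambda = sqrt((c1 + c2)/k); infinite for k = 0."""
        return np.sqrt((self.c1 + self.c2) / self.k) if self.k > 0 else np.inf


def strain_polar(
    u: Callable[[np.ndarray], np.ndarray],
    r: float | np.ndarray,
    du: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strain components (eps_rr, eps_phiphi, eps_rphi) of a radial field.

    For a rotation-invariant displacement u(r) e_r the strain tensor is
    diagonal: eps_rr = du/dr, eps_phiphi = u/r, and the shear component
    eps_rphi vanishes identically.  ``du`` may supply the analytic
    derivative; otherwise a central difference is used (exact for
    polynomials up to cubic order).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InputError("strain_polar requires r > 0")
    if du is not None:
        err = np.asarray(du(r), dtype=float)
    else:
        h = 1e-6 * np.maximum(r, 1.0)
        err = (np.asarray(u(r + h)) - np.asarray(u(r - h))) / (2 * h)
    ephph = np.asarray(u(r), dtype=float) / r
    return err, ephph, np.zeros_like(ephph)


def hooke_stress(
    strain: tuple[np.ndarray, np.ndarray, np.ndarray], c1: float, c2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stress components (sigma_rr, sigma_phiphi, sigma_rphi).

    sigma = c1*eps + c2*I*Tr(eps), hence Tr sigma = (c1+2c2) Tr eps.
    """
    err, ephph, erph = (np.asarray(s, dtype=float) for s in strain)
    tr = err + ephph
    return c1 * err + c2 * tr, c1 * ephph + c2 * tr, c1 * erph


@dataclass
class RadialSolution:
    """Piecewise radial displacement and convergence of a uniform core."""

    params: SheetParams
    coefficients: dict[str, float]
    _u_in: Callable[[np.ndarray], np.ndarray]
    _u_out: Callable[[np.ndarray], np.ndarray]
    _du_in: Callable[[np.ndarray], np.ndarray]
    _du_out: Callable[[np.ndarray], np.ndarray]
    _C_in: Callable[[np.ndarray], np.ndarray]
    _C_out: Callable[[np.ndarray], np.ndarray]

    def _piecewise(self, r, fin, fout) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise InputError("radius must be nonnegative")
        inner = r <= self.params.r0
        out = np.empty(r.shape)
        out[inner] = fin(r[inner])
        out[~inner] = fout(r[~inner])
        return out

    def u(self, r: float | np.ndarray) -> np.ndarray:
        """Radial displacement u(r); negative values point inward."""
        return self._piecewise(r, self._u_in, self._u_out)

    def du(self, r: float | np.ndarray) -> np.ndarray:
        """Radial derivative du/dr."""
        return self._piecewise(r, self._du_in, self._du_out)

    def convergence(self, r: float | np.ndarray) -> np.ndarray:
        """C(r) = -div(u) = -(du/dr + u/r)."""
        return self._piecewise(r, self._C_in, self._C_out)


def solve_uniform_core(params: SheetParams) -> RadialSolution:
    """Equilibrium displacement of a uniformly contracting core.

    See the module docstring for the two branches and their matching
    conditions.
    """
    c1, c2, k, s, r0 = (
        params.c1,
        params.c2,
        params.k,
        params.sigma_star,
        params.r0,
    )
    if k == 0:
        b = -s / (c1 + 2 * c2)
        a = b * r0**2
        return RadialSolution(
            params,
            {"a": a, "b": b},
            _u_in=lambda r: b * r,
            _u_out=lambda r: a / r,
            _du_in=lambda r: np.full_like(r, b),
            _du_out=lambda r: -a / r**2,
            _C_in=lambda r: np.full_like(r, -2 * b),
            _C_out=lambda r: np.zeros_like(r),
        )

    lam = params.lam
    rho0 = r0 / lam
    i1, k1 = special.iv(1, rho0), special.kv(1, rho0)
    # derivatives of I1, K1 at rho0
    di1 = special.iv(0, rho0) - i1 / rho0
    dk1 = -special.kv(0, rho0) - k1 / rho0
    # radial traction of each branch per unit amplitude:
    # sigma_rr = (c1 + c2) u' + c2 u / r
    t_in = (c1 + c2) * di1 / lam + c2 * i1 / r0
    t_out = (c1 + c2) * dk1 / lam + c2 * k1 / r0
    # continuity of u and of total traction sigma_rr + sigma*_rr:
    #   A i1 - B k1 = 0
    #   A t_in - B t_out = -sigma*
    A, B = np.linalg.solve(
        np.array([[i1, -k1], [t_in, -t_out]]), np.array([0.0, -s])
    )
    return RadialSolution(
        params,
        {"A": float(A), "B": float(B), "lambda": lam},
        _u_in=lambda r: A * special.iv(1, r / lam),
        _u_out=lambda r: B * special.kv(1, r / lam),
        _du_in=lambda r: (A / lam)
        * (special.iv(0, r / lam) - special.iv(1, r / lam) / (r / lam)),
        _du_out=lambda r: (B / lam)
        * (-special.kv(0, r / lam) - special.kv(1, r / lam) / (r / lam)),
        _C_in=lambda r: -(A / lam) * special.iv(0, r / lam),
        _C_out=lambda r: (B / lam) * special.kv(0, r / lam),
    )


def response_kernel(r: float | np.ndarray, lam: float) -> np.ndarray:
    """Printed convergence response kernel g(r) = [K1 - K2](r/lam)/(2 lam).

    Negative for every r > 0 (K2 > K1).  Diverges at r = 0, which is
    signalled as an error.
    """
    if lam <= 0:
        raise InputError("lambda must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InputError("response kernel is singular at r = 0")
    x = r / lam
    return (special.kv(1, x) - special.kv(2, x)) / (2 * lam)


@dataclass
class ContractilityField:
    """Nonnegative active-stress distribution sampled on a square lattice.

    ``values[j, i]`` is sigma* at position
    (origin[0] + i*spacing, origin[1] + j*spacing).
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("contractility field must be 2-D")
        if np.any(self.values < 0):
            raise InputError("contractility must be nonnegative")
        if self.spacing <= 0:
            raise InputError("lattice spacing must be positive")

    def node_positions(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)

    @classmethod
    def gaussian(
        cls,
        amplitude: float,
        width: float,
        extent: float,
        n: int,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "ContractilityField":
        """Radially symmetric Gaussian profile on [-extent, extent]^2."""
        x = np.linspace(-extent, extent, n)
        h = x[1] - x[0]
        X, Y = np.meshgrid(x, x)
        r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
        return cls(amplitude * np.exp(-r2 / (2 * width**2)), h, (x[0], x[0]))

    @classmethod
    def uniform_disc(
        cls,
        sigma_star: float,
        r0: float,
        extent: float,
        n: int,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "ContractilityField":
        """Uniform core of radius r0; edge cells weighted by coverage."""
        x = np.linspace(-extent, extent, n)
        h = x[1] - x[0]
        # supersample each cell 4x4 to anti-alias the disc edge
        sub = (np.arange(4) - 1.5) / 4 * h
        X, Y = np.meshgrid(x, x)
        frac = np.zeros_like(X)
        for dx in sub:
            for dy in sub:
                r = np.hypot(X + dx - center[0], Y + dy - center[1])
                frac += (r <= r0).astype(float)
        return cls(sigma_star * frac / 16.0, h, (x[0], x[0]))


def _require_finite_lambda(params: SheetParams) -> float:
    lam = params.lam
    if not np.isfinite(lam):
        raise InputError(
            "k = 0 has no finite decay length; use the closed-form "
            "solve_uniform_core free-sheet branch instead"
        )
    return lam


def _offset_grids(field: ContractilityField) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = field.values.shape
    h = field.spacing
    dy = h * (np.arange(2 * ny - 1) - (ny - 1))
    dx = h * (np.arange(2 * nx - 1) - (nx - 1))
    return np.meshgrid(dx, dy)


def displacement_from_contractility(
    field: ContractilityField, params: SheetParams
) -> np.ndarray:
    """Displacement field on the source lattice, shape (ny, nx, 2).

    Linear response of the adhered sheet: the convolution of sigma* with
    the inward-pointing K1 kernel,

        u(r) = -1/(2 pi lam (c1+c2)) * integral
               sigma*(r') K1(|r - r'|/lam) (r - r')/|r - r'| dr'.

    The singular self-cell contributes zero by symmetry.
    """
    lam = _require_finite_lambda(params)
    h = field.spacing
    DX, DY = _offset_grids(field)
    R = np.hypot(DX, DY)
    mid = R == 0
    R[mid] = 1.0  # placeholder; kernel set to 0 there
    k1 = special.kv(1, R / lam)
    pref = -(h * h) / (2 * np.pi * lam * (params.c1 + params.c2))
    kx = pref * k1 * DX / R
    ky = pref * k1 * DY / R
    kx[mid] = 0.0
    ky[mid] = 0.0
    ux = fftconvolve(field.values, kx, mode="same")
    uy = fftconvolve(field.values, ky, mode="same")
    return np.stack([ux, uy], axis=-1)


def convergence_from_contractility(
    field: ContractilityField, params: SheetParams
) -> np.ndarray:
    """Convergence C = -div(u) on the source lattice.

    The response kernel of the adhered sheet splits into a local term
    and a smooth K0 convolution,

        C(r) = sigma*(r)/(c1+c2)
               - 1/(2 pi lam^2 (c1+c2)) * integral
                 sigma*(r') K0(|r - r'|/lam) dr',

    consistent with taking minus the divergence of the displacement
    response.  The integrable log-singularity of K0 at the self-cell is
    handled by exact integration over an equal-area disc.
    """
    lam = _require_finite_lambda(params)
    h = field.spacing
    ce = params.c1 + params.c2
    DX, DY = _offset_grids(field)
    R = np.hypot(DX, DY)
    mid = R == 0
    R[mid] = 1.0
    kern = special.kv(0, R / lam) * (h * h)
    # self cell: integral of K0(s/lam) over a disc of equal area
    r_eff = h / np.sqrt(np.pi)
    rho_e = r_eff / lam
    kern[mid] = 2 * np.pi * lam**2 * (1.0 - rho_e * special.kv(1, rho_e))
    smooth = fftconvolve(field.values, kern, mode="same") / (
        2 * np.pi * lam**2 * ce
    )
    return field.values / ce - smooth
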