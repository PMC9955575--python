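"""Steady-state signal field on the periodic voxel lattice.

Cells sit at the centers of cubic voxels of side ``H`` (volume
``Vc = H**3``) on a 3D lattice that is periodic on all axes.  Each cell
secretes a single diffusible molecule at rate ``eta0`` (signal node OFF)
or ``alpha * eta0`` (signal node ON).  Because diffusion is much faster
than gene regulation, the concentration field is taken at the steady state
of the diffusion–degradation equation, i.e. the screened Poisson problem

    (gamma - D * Lap_h) C = eta / Vc

with the standard 7-point discrete Laplacian ``Lap_h`` at spacing ``H``.
The solve is spectral (FFT diagonalizes ``Lap_h`` under periodicity) and
exact for the discrete operator: no iterative tolerance is involved.

The decay length of the field is ``sqrt(D / gamma)``; expressed in cell
radii it is the effective interaction distance ``lambda = sqrt(D/gamma)/R``.
Sweeps vary ``lambda`` by varying the degradation rate ``gamma`` at fixed
diffusion coefficient ``D``.

Default calibration: ``R = H/2`` (cell inscribed in its voxel) and
``D = R**2 / Vc``, which puts the uniform basal concentration at
``C00(lambda) = eta0 * lambda**2`` in model units.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "LatticeSpec",
    "FieldParams",
    "gamma_from_lambda",
    "lambda_from_gamma",
    "SteadyStateSolver",
    "solve_steady_state",
    "greens_self",
    "extreme_config_concentrations",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Periodic 3D voxel lattice; one cell per voxel."""

    dims: tuple[int, int, int] = (16, 16, 16)
    H: float = 20.0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.H <= 0:
            raise ValueError("voxel side H must be positive")

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return float(self.H) ** 3


@dataclass(frozen=True)
class FieldParams:
    """Physical parameters of secretion and diffusion.

    ``alpha`` is the active:basal secretion ratio (must exceed 1), ``eta0``
    the basal secretion rate, ``R`` the cell radius and ``D`` the diffusion
    coefficient.  The degradation rate is not stored: it is derived from
    the effective interaction distance via :func:`gamma_from_lambda`.
    """

    D: float = 0.0125
    R: float = 10.0
    alpha: float = 5.0
    eta0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.D, self.R, self.eta0) <= 0:
            raise ValueError("D, R and eta0 must be strictly positive")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 (active > basal secretion)")

    def secretion_rates(self, signal_bits: np.ndarray) -> np.ndarray:
        """Per-cell secretion rate eta(x_S): eta0 if OFF, alpha*eta0 if ON."""
        bits = np.asarray(signal_bits)
        return self.eta0 * (1.0 + (self.alpha - 1.0) * bits)


def gamma_from_lambda(lam: float, D: float, R: float) -> float:
    """Degradation rate realizing interaction distance ``lam`` (in cell
    radii): ``gamma = D / (lam * R)**2``."""
    if min(lam, D, R) <= 0:
        raise ValueError("lambda, D and R must be strictly positive")
    return D / (lam * R) ** 2


def lambda_from_gamma(gamma: float, D: float, R: float) -> float:
    """Inverse of :func:`gamma_from_lambda`: ``sqrt(D/gamma) / R``."""
    if min(gamma, D, R) <= 0:
        raise ValueError("gamma, D and R must be strictly positive")
    return float(np.sqrt(D / gamma) / R)


class SteadyStateSolver:
    """Spectral solver for ``(gamma - D*Lap_h) C = eta / Vc``.

    Precomputes the Fourier symbol once; each :meth:`solve` is one
    real-to-complex FFT round trip.  The 7-point Laplacian eigenvalue for
    mode ``(kx, ky, kz)`` on an ``(nx, ny, nz)`` periodic grid with
    spacing ``H`` is ``(2/H^2) * sum_axis (cos(2 pi k/n) - 1)``, which is
    nonpositive, so the symbol ``gamma - D*eig`` is bounded below by
    ``gamma > 0`` and the problem is always well posed.
    """

    def __init__(self, lattice: LatticeSpec, D: float, gamma: float) -> None:
        if gamma <= 0 or D <= 0:
            raise ValueError("D and gamma must be strictly positive")
        self.lattice = lattice
        self.D = float(D)
        self.gamma = float(gamma)
        nx, ny, nz = lattice.dims
        h2 = lattice.H**2

        def eig(n: int, real: bool = False) -> np.ndarray:
            freqs = np.arange(n // 2 + 1) if real else np.arange(n)
            return 2.0 * (np.cos(2.0 * np.pi * freqs / n) - 1.0) / h2

        lap = (
            eig(nx)[:, None, None]
            + eig(ny)[None, :, None]
            + eig(nz, real=True)[None, None, :]
        )
        self._inv_symbol = 1.0 / (self.gamma - self.D * lap)

    def solve(self, secretion: np.ndarray) -> np.ndarray:
        """Steady-state concentration for per-voxel secretion rates
        ``eta`` (shape = lattice dims); the source term is ``eta / Vc``."""
        eta = np.asarray(secretion, dtype=np.float64)
        if eta.shape != self.lattice.dims:
            raise ValueError(
                f"secretion shape {eta.shape} != lattice dims {self.lattice.dims}"
            )
        rhs = eta / self.lattice.voxel_volume
        c = np.fft.irfftn(
            np.fft.rfftn(rhs) * self._inv_symbol,
            s=self.lattice.dims,
            axes=(0, 1, 2),
        )
        # the continuous operator preserves positivity; clip FFT round-off
        return np.maximum(c, 0.0)


def solve_steady_state(
    secretion: np.ndarray,
    lattice: LatticeSpec,
    D: float,
    gamma: float,
) -> np.ndarray:
    """One-shot convenience wrapper around :class:`SteadyStateSolver`."""
    return SteadyStateSolver(lattice, D, gamma).solve(secretion)


def greens_self(lattice: LatticeSpec, D: float, gamma: float) -> float:
    """Concentration at the source voxel for a unit secretion rate there.

    ``G0 = G(0)`` of the discrete Green's function of
    ``(gamma - D*Lap_h)(.) * Vc``.  The total over all voxels is
    ``1 / (gamma * Vc)`` (integrate the discrete equation; the Laplacian
    telescopes under periodic boundaries).
    """
    eta = np.zeros(lattice.dims)
    eta[0, 0, 0] = 1.0
    return float(SteadyStateSolver(lattice, D, gamma).solve(eta)[0, 0, 0])


def extreme_config_concentrations(
    lam: float,
    params: FieldParams,
    lattice: LatticeSpec,
) -> tuple[float, float, float, float]:
    """Focal-cell concentrations under the four extreme signal configurations.

    Returns ``(C00, C01, C10, C11)`` where the first bit is the focal
    cell's own signal state and the second is the common signal state of
    all other cells.  By linearity of the steady-state operator only one
    Green's-function solve is needed:

    - ``C00 = eta0 / (gamma * Vc)``        (uniform basal field)
    - ``C11 = alpha * C00``                (uniform active field)
    - ``C10 = C00 + (alpha-1) * eta0 * G0``
    - ``C01 = C00 + C11 - C10``
    """
    gamma = gamma_from_lambda(lam, params.D, params.R)
    c00 = params.eta0 / (gamma * lattice.voxel_volume)
    c11 = params.alpha * c00
    g0 = greens_self(lattice, params.D, gamma)
    c10 = c00 + (params.alpha - 1.0) * params.eta0 * g0
    c01 = c00 + c11 - c10
    return (c00, c01, c10, c11)
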