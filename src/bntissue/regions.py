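"""Signaling-region classification in the (lambda, theta) plane.

The probe is a tissue of two-node cells — a constant signal node (it
copies its own previous value) and a threshold receptor.  For a focal
cell the receptor response after one step depends only on which of the
four extreme-configuration concentrations ``C00 < {C01, C10} < C11``
exceed theta, where the two bits of ``Cab`` are (own signal, everyone
else's signal).  The resulting 4-bit response vector ``(r00, r01, r10,
r11)`` takes exactly six admissible values, splitting the plane into
three asocial regions (receptor insensitive to neighbors) and three
social ones:

====== =============== ==========================================
label  response        meaning
====== =============== ==========================================
A1     (1,1,1,1)       ON: basal secretion already activates
S1     (0,1,1,1)       self OR neighbors activate
A2     (0,0,1,1)       SELF: only own signal activates
S2     (0,1,0,1)       neighbors activate, own signal cannot
S3     (0,0,0,1)       self AND neighbors needed
A3     (0,0,0,0)       OFF: even full activation is below theta
====== =============== ==========================================

The four boundary curves are the concentrations ``C00(lam) < C01, C10 <
C11(lam)`` themselves; which of A2/S2 occupies the middle band flips at
the single crossover ``lambda*`` where the self contribution equals the
total neighbor contribution (``C01 = C10``).
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .field import FieldParams, LatticeSpec, extreme_config_concentrations
from .network import BooleanNetwork
from .tissue import Tissue, step

__all__ = [
    "REGION_BY_RESPONSE",
    "two_node_network",
    "response_vector",
    "classify_response",
    "classify_point",
    "boundary_curves",
    "crossover_lambda",
    "region_map",
    "place_thetas",
    "six_region_samples",
]

#: Bijection between admissible response vectors and region labels.
REGION_BY_RESPONSE: dict[tuple[int, int, int, int], str] = {
    (1, 1, 1, 1): "A1",
    (0, 1, 1, 1): "S1",
    (0, 0, 1, 1): "A2",
    (0, 1, 0, 1): "S2",
    (0, 0, 0, 1): "S3",
    (0, 0, 0, 0): "A3",
}

ASOCIAL = frozenset({"A1", "A2", "A3"})
SOCIAL = frozenset({"S1", "S2", "S3"})


def two_node_network() -> BooleanNetwork:
    """The probe cell: constant signal node (self-loop identity truth
    table) plus the threshold receptor; no regulatory nodes."""
    return BooleanNetwork(
        n_regulatory=0,
        k=1,
        wiring=np.array([[0]]),  # signal reads itself
        truth_tables=np.array([[0, 1]], dtype=np.uint8),
    )


def response_vector(
    lam: float,
    theta: float,
    params: FieldParams,
    lattice: LatticeSpec,
    method: Literal["curves", "simulate"] = "curves",
) -> tuple[int, int, int, int]:
    """Receptor response of a focal cell to the four extreme signal
    configurations.

    ``method='curves'`` thresholds the four analytically assembled
    concentrations; ``method='simulate'`` literally builds the four
    two-node tissue samples, advances each one synchronous step and reads
    the focal receptor — the two must agree exactly (same discrete
    operator) and the simulate path exists as a cross-check.
    """
    if method == "curves":
        c = extreme_config_concentrations(lam, params, lattice)
        return tuple(int(ci > theta) for ci in c)  # type: ignore[return-value]
    net = two_node_network()
    bits = []
    for self_bit, others_bit in ((0, 0), (0, 1), (1, 0), (1, 1)):
        states = np.zeros((lattice.n_cells, net.n_total), dtype=np.uint8)
        states[:, net.signal_index] = others_bit
        states[0, net.signal_index] = self_bit
        tissue = Tissue(net, lattice, params, lam, theta, states)
        bits.append(int(step(tissue).states[0, net.receptor_index]))
    return tuple(bits)  # type: ignore[return-value]


def classify_response(vector: Iterable[int]) -> str:
    """Map an admissible response vector to its region label.

    Raises ``ValueError`` for vectors violating monotonicity (more
    secretion can never lower the concentration, so r00 <= r01, r10 <=
    r11); such a vector signals a solver bug upstream.
    """
    vec = tuple(int(b) for b in vector)
    if len(vec) != 4 or any(b not in (0, 1) for b in vec):
        raise ValueError(f"response vector must be 4 bits, got {vec}")
    label = REGION_BY_RESPONSE.get(vec)
    if label is None:
        raise ValueError(f"non-monotone response vector {vec}")
    return label


def classify_point(
    lam: float, theta: float, params: FieldParams, lattice: LatticeSpec
) -> str:
    """Region label of a single (lambda, theta) point."""
    return classify_response(response_vector(lam, theta, params, lattice))


def boundary_curves(
    lambda_grid: Iterable[float],
    params: FieldParams,
    lattice: LatticeSpec,
) -> pd.DataFrame:
    """The four concentration curves over a lambda grid.

    Returns a DataFrame with columns ``lam, C00, C01, C10, C11``.  At
    fixed lambda, ascending theta crosses the sorted curves and traverses
    A1 -> S1 -> (A2 if C10 > C01 else S2) -> S3 -> A3.
    """
    rows = []
    for lam in lambda_grid:
        c00, c01, c10, c11 = extreme_config_concentrations(float(lam), params, lattice)
        rows.append((float(lam), c00, c01, c10, c11))
    if not rows:
        raise ValueError("lambda grid is empty")
    return pd.DataFrame(rows, columns=["lam", "C00", "C01", "C10", "C11"])


def crossover_lambda(
    params: FieldParams,
    lattice: LatticeSpec,
    bracket: tuple[float, float] = (0.05, 20.0),
) -> float:
    """The lambda at which the self and total-neighbor contributions are
    equal (C01 = C10), separating the A2 band (below) from S2 (above).

    Equivalent to ``G0(lambda) = 1 / (2 * gamma * Vc)``: the Green's
    function mass at the source voxel equals half the total mass.
    """

    def f(lam: float) -> float:
        c00, c01, c10, c11 = extreme_config_concentrations(lam, params, lattice)
        return (c10 - c01) / c00  # scale-free

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo <= 0 or fhi >= 0:
        raise ValueError(
            f"bracket {bracket} does not straddle the C01/C10 crossover "
            f"(f(lo)={flo:.3g}, f(hi)={fhi:.3g})"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def region_map(
    lambda_grid: Iterable[float],
    theta_grid: Iterable[float],
    params: FieldParams,
    lattice: LatticeSpec,
) -> tuple[pd.DataFrame, int]:
    """Classify every point of a (lambda, theta) grid.

    Returns a long-format DataFrame ``(lam, theta, label)`` and the
    number of distinct labels observed.  With theta spanning below
    ``min C00`` to above ``max C11`` and lambda spanning the C01/C10
    crossover, all six regions appear.
    """
    thetas = np.asarray(list(theta_grid), dtype=float)
    if thetas.size == 0:
        raise ValueError("theta grid is empty")
    curves = boundary_curves(lambda_grid, params, lattice)
    frames = []
    for row in curves.itertuples(index=False):
        c = np.array([row.C00, row.C01, row.C10, row.C11])
        bits = (c[None, :] > thetas[:, None]).astype(int)  # (n_theta, 4)
        labels = [REGION_BY_RESPONSE[tuple(b)] for b in bits]
        frames.append(pd.DataFrame({"lam": row.lam, "theta": thetas, "label": labels}))
    table = pd.concat(frames, ignore_index=True)
    return table, int(table["label"].nunique())


def place_thetas(
    lam: float,
    params: FieldParams,
    lattice: LatticeSpec,
    n_mid: int = 5,
) -> tuple[np.ndarray, list[str]]:
    """Curve-relative theta placement at one lambda.

    Mirrors the sweep sampling rule: 1 threshold in A1, 1 in S1, ``n_mid``
    uniformly inside the middle band (A2 below the crossover, S2 above),
    1 in S3 and 1 in A3.  Absolute units follow the field calibration, so
    placement is expressed as fractions/means of the computed curves.
    """
    c00, c01, c10, c11 = extreme_config_concentrations(lam, params, lattice)
    lo, hi = min(c01, c10), max(c01, c10)
    mid = np.linspace(lo, hi, n_mid + 2)[1:-1]
    thetas = np.concatenate(
        [[0.5 * c00, np.sqrt(c00 * lo)], mid, [np.sqrt(hi * c11), 2.0 * c11]]
    )
    labels = [classify_point(lam, t, params, lattice) for t in thetas]
    return thetas, labels


def six_region_samples(
    params: FieldParams,
    lattice: LatticeSpec,
    lam_ref: float = 1.5,
    lam_grid_step: float = 0.5,
) -> list[tuple[str, float, float]]:
    """One (lambda, theta) sample in each of the six regions.

    A2 and S2 occupy the same theta band on opposite sides of the
    crossover lambda*, so the A2 sample sits at the largest grid multiple
    of ``lam_grid_step`` below lambda* and the S2 sample at the smallest
    multiple above; the four remaining regions are sampled at
    ``lam_ref``.  Returns ``[(label, lam, theta), ...]`` and checks
    each placed point classifies as intended.
    """
    lam_star = crossover_lambda(params, lattice)
    lam_a2 = lam_grid_step * max(1.0, np.floor(lam_star / lam_grid_step))
    if lam_a2 >= lam_star:
        lam_a2 = 0.5 * lam_star
    lam_s2 = lam_grid_step * np.ceil(lam_star / lam_grid_step)
    if lam_s2 <= lam_star:
        lam_s2 += lam_grid_step

    def band_mid(lam: float) -> float:
        c00, c01, c10, c11 = extreme_config_concentrations(lam, params, lattice)
        return float(np.sqrt(min(c01, c10) * max(c01, c10)))

    c00, c01, c10, c11 = extreme_config_concentrations(lam_ref, params, lattice)
    lo, hi = min(c01, c10), max(c01, c10)
    samples = [
        ("A1", lam_ref, 0.5 * c00),
        ("S1", lam_ref, float(np.sqrt(c00 * lo))),
        ("A2", float(lam_a2), band_mid(float(lam_a2))),
        ("S2", float(lam_s2), band_mid(float(lam_s2))),
        ("S3", lam_ref, float(np.sqrt(hi * c11))),
        ("A3", lam_ref, 2.0 * c11),
    ]
    for label, lam, theta in samples:
        got = classify_point(lam, theta, params, lattice)
        if got != label:
            raise RuntimeError(
                f"sample placement failed: ({lam}, {theta}) classified {got}, "
                f"wanted {label}"
            )
    return samples
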