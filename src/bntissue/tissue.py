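"""Coupled tissue dynamics and attractor detection.

A tissue is ``N = nx*ny*nz`` cells, one per voxel, all described by the
same Boolean network.  One synchronous time step is:

1. solve the steady-state concentration field from the signal bits at
   time ``t``;
2. set every cell's receptor to 1 iff the concentration at its own voxel
   strictly exceeds the activation threshold ``theta``;
3. update every cell's regulatory and signal nodes from its state at
   time ``t``.

The coupled system is a deterministic finite dynamical system, so every
trajectory is eventually periodic.  A tissue sample has reached its
attractor once the *global* state (all nodes of all cells) revisits a
previously seen state; the attractor is the recurrent cycle and each
cell's cellular attractor (CA) is the SET of states it visits over that
cycle, order discarded.

Cells are indexed by C-order flattening of the ``(nx, ny, nz)`` lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .field import FieldParams, LatticeSpec, SteadyStateSolver, gamma_from_lambda
from .network import BooleanNetwork, update_internal

__all__ = [
    "Tissue",
    "TissueAttractor",
    "make_tissue",
    "step",
    "run_to_attractor",
    "run_asocial_reference",
    "unique_cellular_attractors",
    "cell_state_codes",
]

ReceptorMode = Literal["field", "on", "off", "self"]


@dataclass(frozen=True)
class Tissue:
    """A tissue sample: shared network + lattice + signaling parameters +
    the current N x n_total bit matrix."""

    network: BooleanNetwork
    lattice: LatticeSpec
    params: FieldParams
    lam: float
    theta: float
    states: np.ndarray  # (N, n_total) uint8
    t: int = 0

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.uint8)
        expected = (self.lattice.n_cells, self.network.n_total)
        if states.shape != expected:
            raise ValueError(f"states must have shape {expected}, got {states.shape}")
        object.__setattr__(self, "states", states)
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def n_cells(self) -> int:
        return self.lattice.n_cells

    @property
    def signal_bits(self) -> np.ndarray:
        return self.states[:, self.network.signal_index]


def make_tissue(
    network: BooleanNetwork,
    lattice: LatticeSpec,
    params: FieldParams,
    lam: float,
    theta: float,
    rng: np.random.Generator | None = None,
    states: np.ndarray | None = None,
) -> Tissue:
    """Build a tissue sample, drawing each node of each cell 0/1 with
    probability 1/2 from ``rng`` unless explicit ``states`` are given."""
    if states is None:
        if rng is None:
            raise ValueError("provide either rng or explicit states")
        states = network.random_state(rng, n_cells=lattice.n_cells)
    return Tissue(network, lattice, params, lam, theta, states)


class _Stepper:
    """Cached one-step propagator for a tissue sample.

    ``mode='field'`` is the full coupled dynamics.  Modes ``'on'``,
    ``'off'`` and ``'self'`` replace the receptor rule with the constant
    behavior of the three asocial regions (always active, never active,
    mirror own signal); in those regimes cells are closed systems and no
    field solve is needed, but the receptor update is *exactly* what a
    tissue sample placed inside the corresponding region computes.
    """

    def __init__(self, tissue: Tissue, mode: ReceptorMode = "field") -> None:
        self.tissue = tissue
        self.mode = mode
        self._solver: SteadyStateSolver | None = None
        if mode == "field":
            gamma = gamma_from_lambda(tissue.lam, tissue.params.D, tissue.params.R)
            self._solver = SteadyStateSolver(tissue.lattice, tissue.params.D, gamma)

    def receptor_next(self, states: np.ndarray) -> np.ndarray:
        net = self.tissue.network
        if self.mode == "on":
            return np.ones(states.shape[0], dtype=np.uint8)
        if self.mode == "off":
            return np.zeros(states.shape[0], dtype=np.uint8)
        if self.mode == "self":
            return states[:, net.signal_index]
        assert self._solver is not None
        eta = self.tissue.params.secretion_rates(states[:, net.signal_index])
        conc = self._solver.solve(eta.reshape(self.tissue.lattice.dims))
        return (conc.reshape(-1) > self.tissue.theta).astype(np.uint8)

    def advance(self, states: np.ndarray) -> np.ndarray:
        return update_internal(self.tissue.network, states, self.receptor_next(states))


def step(tissue: Tissue, mode: ReceptorMode = "field") -> Tissue:
    """Advance a tissue sample by one synchronous time step."""
    nxt = _Stepper(tissue, mode).advance(tissue.states)
    return replace(tissue, states=nxt, t=tissue.t + 1)


@dataclass(frozen=True)
class TissueAttractor:
    """Result of attractor detection.

    ``found`` is False on timeout, in which case ``period`` is 0 and
    ``cycle`` is empty.  ``recurrence_time = transient + period`` is the
    step index at which the global state first revisited a seen state.
    """

    found: bool
    transient: int
    period: int
    cycle: tuple[np.ndarray, ...]  # period states of shape (N, n_total)

    @property
    def recurrence_time(self) -> int:
        return self.transient + self.period

    def cell_attractors(self) -> list[frozenset[int]]:
        """Per-cell cellular attractor: the set of that cell's states over
        the cycle, each state encoded as an integer bit pattern."""
        if not self.found:
            raise ValueError("no attractor was found (timeout)")
        codes = np.stack([cell_state_codes(s) for s in self.cycle])  # (tau, N)
        return [frozenset(int(c) for c in codes[:, i]) for i in range(codes.shape[1])]


def cell_state_codes(states: np.ndarray) -> np.ndarray:
    """Encode each row of an (N, n_total) bit matrix as a big-endian
    integer (node 0 most significant)."""
    states = np.asarray(states, dtype=np.uint64)
    n = states.shape[-1]
    powers = (np.uint64(1) << np.arange(n - 1, -1, -1, dtype=np.uint64))
    return states @ powers


def _run(stepper: _Stepper, states: np.ndarray, max_steps: int) -> TissueAttractor:
    seen: dict[bytes, int] = {}
    trace: list[np.ndarray] = []
    cur = np.ascontiguousarray(states, dtype=np.uint8)
    for t in range(max_steps + 1):
        key = np.packbits(cur).tobytes()
        t0 = seen.get(key)
        if t0 is not None:
            cycle = tuple(trace[t0:t])
            return TissueAttractor(True, transient=t0, period=t - t0, cycle=cycle)
        seen[key] = t
        trace.append(cur)
        if t == max_steps:
            break
        cur = stepper.advance(cur)
    return TissueAttractor(False, transient=max_steps, period=0, cycle=())


def run_to_attractor(
    tissue: Tissue,
    max_steps: int = 2000,
    mode: ReceptorMode = "field",
) -> TissueAttractor:
    """Iterate the coupled dynamics until the global state first recurs.

    Detection is by exact hashing of the packed global bit matrix, so the
    returned cycle satisfies ``step(last) == first`` bit for bit.  If no
    recurrence happens within ``max_steps`` steps a timeout result
    (``found=False``) is returned, not an exception.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    return _run(_Stepper(tissue, mode), tissue.states, max_steps)


def run_asocial_reference(
    network: BooleanNetwork,
    lattice: LatticeSpec,
    params: FieldParams,
    states: np.ndarray,
    mode: Literal["on", "off", "self"],
    max_steps: int = 2000,
) -> TissueAttractor:
    """Attractor of the tissue under one of the three asocial regimes.

    Within an asocial region the receptor rule is independent of theta,
    lambda and the other cells' states (ON region: always 1; OFF region:
    always 0; SELF region: receptor mirrors the cell's own signal), so
    the reference dynamics can be run without any field solve.  The
    result is identical to running the full coupled dynamics at any
    (lambda, theta) inside that region.
    """
    tissue = Tissue(network, lattice, params, lam=1.0, theta=0.0, states=states)
    return _run(_Stepper(tissue, mode), tissue.states, max_steps)


def unique_cellular_attractors(
    attractor: TissueAttractor,
) -> tuple[list[frozenset[int]], np.ndarray]:
    """Deduplicate per-cell CAs by state-set equality.

    Returns the list of distinct CAs (in order of first appearance by
    cell index) and, for each cell, the index of its CA in that list.
    """
    cas = attractor.cell_attractors()
    catalogue: dict[frozenset[int], int] = {}
    assignment = np.empty(len(cas), dtype=np.intp)
    for i, ca in enumerate(cas):
        idx = catalogue.setdefault(ca, len(catalogue))
        assignment[i] = idx
    return list(catalogue), assignment
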