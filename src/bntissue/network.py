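"""Per-cell Boolean networks with a signal/receptor node pair.

A cell is a Boolean network over ``n_total = n_regulatory + 2`` binary
nodes: ``n_regulatory`` regulatory nodes (indices ``0 .. n_regulatory-1``),
one signal node (index ``n_regulatory``) and one receptor node (index
``n_regulatory + 1``).  Regulatory nodes and the signal node are
*updatable*: each carries an ordered list of ``k`` input nodes and a truth
table of ``2**k`` output bits.  The receptor node has no truth table — it
is set by thresholding the local concentration of the diffusible signal,
which is computed outside this module and passed in as ``receptor_next``.

Truth-table indexing convention
-------------------------------
The input tuple ``(x_{j1}, ..., x_{jk})`` is read as a big-endian binary
integer: the *first* wired input is the most significant bit.  Row ``0``
therefore corresponds to all inputs 0 and row ``2**k - 1`` to all inputs 1.

The signal node is never wired as an input of any *other* node, keeping
secretion distinct from internal regulation.  The single sanctioned
exception is a self-loop on the signal node itself, which is how a
constant-signal cell (signal copies its own previous value) is expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "critical_bias",
    "generate_rbn",
    "update_internal",
    "is_receptor_disconnected",
    "read_network",
    "write_network",
]


@dataclass(frozen=True)
class BooleanNetwork:
    """Shared per-cell Boolean network (wiring + truth tables).

    Parameters
    ----------
    n_regulatory:
        Number of regulatory nodes.
    k:
        Common in-degree of every updatable node.
    wiring:
        Integer array of shape ``(n_regulatory + 1, k)``; row ``j`` lists
        the ordered input node ids of updatable node ``j`` (regulatory
        nodes first, signal node last).
    truth_tables:
        ``uint8`` array of shape ``(n_regulatory + 1, 2**k)``; row ``j``
        is the truth table of updatable node ``j`` in big-endian input
        order.
    """

    n_regulatory: int
    k: int
    wiring: np.ndarray
    truth_tables: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wiring", np.asarray(self.wiring, dtype=np.intp))
        object.__setattr__(
            self, "truth_tables", np.asarray(self.truth_tables, dtype=np.uint8)
        )
        self.validate()

    # -- derived indices ---------------------------------------------------
    @property
    def n_total(self) -> int:
        return self.n_regulatory + 2

    @property
    def signal_index(self) -> int:
        return self.n_regulatory

    @property
    def receptor_index(self) -> int:
        return self.n_regulatory + 1

    @property
    def n_updatable(self) -> int:
        """Regulatory nodes plus the signal node."""
        return self.n_regulatory + 1

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_regulatory < 0:
            raise ValueError("n_regulatory must be >= 0")
        if self.k < 1:
            raise ValueError("in-degree k must be >= 1")
        if self.wiring.shape != (self.n_updatable, self.k):
            raise ValueError(
                f"wiring must have shape {(self.n_updatable, self.k)}, "
                f"got {self.wiring.shape}"
            )
        if self.truth_tables.shape != (self.n_updatable, 2**self.k):
            raise ValueError(
                f"truth_tables must have shape {(self.n_updatable, 2 ** self.k)}, "
                f"got {self.truth_tables.shape}"
            )
        if self.wiring.min(initial=0) < 0 or self.wiring.max(initial=0) >= self.n_total:
            raise ValueError("wiring refers to node ids outside the network")
        # The signal node feeds no other node; a self-loop on the signal
        # node itself is allowed (constant-signal cells).
        sig = self.signal_index
        for j in range(self.n_updatable):
            if j != sig and sig in self.wiring[j]:
                raise ValueError("signal node may not be an input of another node")
        if not np.isin(self.truth_tables, (0, 1)).all():
            raise ValueError("truth tables must be binary")

    # -- queries -----------------------------------------------------------
    def random_state(self, rng: np.random.Generator, n_cells: int | None = None) -> np.ndarray:
        """Draw node values 0/1 with probability 1/2 each, independently."""
        shape = (self.n_total,) if n_cells is None else (n_cells, self.n_total)
        return (rng.random(shape) < 0.5).astype(np.uint8)


def critical_bias(k: int) -> float:
    """Truth-table bias placing a random Boolean network at criticality.

    The order/chaos boundary of a random Boolean network with constant
    in-degree ``k`` and bias ``p`` sits where the average sensitivity
    ``2 k p (1 - p)`` equals 1.  This returns the smaller root of that
    quadratic, ``p = (1 - sqrt(1 - 2/k)) / 2``.

    Raises
    ------
    ValueError
        If ``k < 2`` (no real root exists for ``k < 2``; ``k = 2`` gives
        exactly ``p = 1/2``).
    """
    if k < 2:
        raise ValueError(f"no real critical bias exists for k={k} (need k >= 2)")
    return 0.5 * (1.0 - math.sqrt(1.0 - 2.0 / k))


def generate_rbn(
    n_regulatory: int,
    k: int,
    p: float,
    rng: np.random.Generator,
) -> BooleanNetwork:
    """Draw a random Boolean network in the classic Kauffman NK fashion.

    Every updatable node (the ``n_regulatory`` regulatory nodes and the
    signal node) receives ``k`` *distinct* inputs drawn uniformly from the
    regulatory nodes and the receptor node; the signal node is never a
    candidate input.  Each truth-table bit is 1 with probability ``p``,
    independently.
    """
    if n_regulatory < 1:
        raise ValueError("n_regulatory must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("bias p must lie strictly between 0 and 1")
    candidates = np.array(
        list(range(n_regulatory)) + [n_regulatory + 1], dtype=np.intp
    )  # regulatory nodes + receptor
    if k > candidates.size:
        raise ValueError(
            f"k={k} exceeds the {candidates.size} available distinct input nodes"
        )
    n_upd = n_regulatory + 1
    wiring = np.empty((n_upd, k), dtype=np.intp)
    for j in range(n_upd):
        wiring[j] = rng.choice(candidates, size=k, replace=False)
    truth_tables = (rng.random((n_upd, 2**k)) < p).astype(np.uint8)
    return BooleanNetwork(n_regulatory, k, wiring, truth_tables)


def update_internal(
    network: BooleanNetwork,
    state: np.ndarray,
    receptor_next: np.ndarray | int,
) -> np.ndarray:
    """One synchronous update of the regulatory and signal nodes.

    ``state`` is either a single cell state of shape ``(n_total,)`` or a
    stack of cell states of shape ``(N, n_total)``.  All truth-function
    reads are taken from ``state``; the receptor bit of the result is set
    to ``receptor_next`` (computed elsewhere from the concentration field
    at the same time step).
    """
    state = np.asarray(state, dtype=np.uint8)
    if state.shape[-1] != network.n_total:
        raise ValueError(
            f"state has {state.shape[-1]} nodes, network expects {network.n_total}"
        )
    powers = 1 << np.arange(network.k - 1, -1, -1)  # big-endian
    inputs = state[..., network.wiring]  # (..., n_upd, k)
    idx = inputs @ powers  # (..., n_upd)
    nxt = np.empty_like(state)
    nxt[..., : network.n_updatable] = network.truth_tables[
        np.arange(network.n_updatable), idx
    ]
    nxt[..., network.receptor_index] = receptor_next
    return nxt


def is_receptor_disconnected(network: BooleanNetwork) -> bool:
    """True iff the receptor feeds no updatable node.

    In that case the concentration field can never influence the cell and
    the tissue behaves as independent closed cells for every (λ, θ).
    """
    return not bool(np.any(network.wiring == network.receptor_index))


# ---------------------------------------------------------------------------
# plain-text network file format
#
#   # optional comment lines
#   n_reg k
#   node_id : i1,i2,...,ik : b0b1...b_{2^k-1}     (one line per updatable node)
# ---------------------------------------------------------------------------

def write_network(network: BooleanNetwork, path: str | Path) -> None:
    """Write a network to the plain-text format (round-trips with
    :func:`read_network`)."""
    lines = [f"{network.n_regulatory} {network.k}"]
    for j in range(network.n_updatable):
        ins = ",".join(str(int(i)) for i in network.wiring[j])
        bits = "".join(str(int(b)) for b in network.truth_tables[j])
        lines.append(f"{j} : {ins} : {bits}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> BooleanNetwork:
    """Read a network from the plain-text format written by
    :func:`write_network`."""
    raw = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not raw:
        raise ValueError(f"empty network file: {path}")
    header = raw[0].split()
    if len(header) != 2:
        raise ValueError("header must be 'n_reg k'")
    n_reg, k = int(header[0]), int(header[1])
    n_upd = n_reg + 1
    if len(raw) - 1 != n_upd:
        raise ValueError(
            f"expected {n_upd} node lines for n_reg={n_reg}, got {len(raw) - 1}"
        )
    wiring = np.empty((n_upd, k), dtype=np.intp)
    tables = np.empty((n_upd, 2**k), dtype=np.uint8)
    seen: set[int] = set()
    for ln in raw[1:]:
        parts = [p.strip() for p in ln.split(":")]
        if len(parts) != 3:
            raise ValueError(f"malformed node line: {ln!r}")
        j = int(parts[0])
        if j in seen or not 0 <= j < n_upd:
            raise ValueError(f"bad or duplicate node id {j}")
        seen.add(j)
        ins = [int(s) for s in parts[1].split(",")]
        if len(ins) != k:
            raise ValueError(f"node {j}: expected {k} inputs, got {len(ins)}")
        bits = parts[2]
        if len(bits) != 2**k or set(bits) - {"0", "1"}:
            raise ValueError(f"node {j}: truth table must be {2 ** k} binary digits")
        wiring[j] = ins
        tables[j] = [int(c) for c in bits]
    return BooleanNetwork(n_reg, k, wiring, tables)
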