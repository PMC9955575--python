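"""Experiment drivers: region scan, ensemble sweep, fixtures.

The two canonical experiment designs are

- a *region scan*: classify a fine (lambda, theta) grid with the
  two-node probe cell and export the region map and the four boundary
  curves;
- an *ensemble sweep*: generate random critical 12-node cellular
  networks, run each tissue at a grid of (lambda, theta) samples placed
  curve-relative so that every signaling region is represented, and
  compute per-sample attractors, population metrics and the lost/novel
  CA taxonomy against the asocial references.

Every run is fully determined by (config, master seed): the master seed
is spawned into independent child streams, one per tissue, used for
network wiring/truth tables and the initial states.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .field import FieldParams, LatticeSpec
from .metrics import (
    b_metric,
    ca_distribution,
    dkl_hat,
    is_homogeneous,
    tissue_entropy,
)
from .network import (
    BooleanNetwork,
    critical_bias,
    generate_rbn,
    is_receptor_disconnected,
    write_network,
)
from .regions import (
    ASOCIAL,
    boundary_curves,
    place_thetas,
    region_map,
    six_region_samples,
    two_node_network,
)
from .taxonomy import CACatalogue, novel_lambda_stats
from .tissue import (
    Tissue,
    TissueAttractor,
    run_asocial_reference,
    run_to_attractor,
    unique_cellular_attractors,
)

__all__ = [
    "SweepConfig",
    "run_region_scan",
    "run_sweep",
    "run_attractor_horizon",
    "make_fixtures",
    "three_node_toy_network",
]

_CSV_FLOAT = "%.10g"


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of an ensemble sweep.

    Defaults mirror the reference experiment at desk scale: critical
    12-node cells (10 regulatory + signal/receptor pair, k=3,
    p = critical_bias(3)) on a 16^3 periodic lattice, 12 interaction
    distances in steps of 0.5 cell radii, and 9 curve-relative receptor
    thresholds per lambda (1 in A1, 1 in S1, 5 across the A2/S2 band,
    1 in S3, 1 in A3).  ``n_tissues`` defaults to 10; the 100-tissue
    ensemble is a long-running opt-in.
    """

    n_tissues: int = 10
    n_regulatory: int = 10
    k: int = 3
    p: float | None = None  # None -> critical_bias(k)
    dims: tuple[int, int, int] = (16, 16, 16)
    H: float = 20.0
    D: float = 0.0125
    R: float = 10.0
    alpha: float = 5.0
    eta0: float = 1.0
    lambdas: tuple[float, ...] = tuple(0.5 * i for i in range(1, 13))
    n_theta_mid: int = 5
    max_steps: int = 2000
    epsilon: float = 1e-6
    seed: int = 0

    @property
    def bias(self) -> float:
        return critical_bias(self.k) if self.p is None else self.p

    @property
    def lattice(self) -> LatticeSpec:
        return LatticeSpec(self.dims, self.H)

    @property
    def field_params(self) -> FieldParams:
        return FieldParams(D=self.D, R=self.R, alpha=self.alpha, eta0=self.eta0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bias"] = self.bias
        return d


# ---------------------------------------------------------------------------
# region scan
# ---------------------------------------------------------------------------

def run_region_scan(
    params: FieldParams,
    lattice: LatticeSpec,
    lambda_grid: Sequence[float],
    theta_grid: Sequence[float] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Classify a (lambda, theta) grid and export map + boundary curves.

    When ``theta_grid`` is None a logarithmic grid spanning from half
    the smallest C00 to twice the largest C11 (200 points) is used, so
    every band that exists somewhere on the lambda grid is sampled.
    Returns a manifest dict; writes ``region_map.csv``,
    ``boundary_curves.csv`` and ``manifest.json`` when ``outdir`` given.
    """
    curves = boundary_curves(lambda_grid, params, lattice)
    if theta_grid is None:
        lo = 0.5 * curves["C00"].min()
        hi = 2.0 * curves["C11"].max()
        theta_grid = np.geomspace(lo, hi, 200)
    table, n_distinct = region_map(lambda_grid, theta_grid, params, lattice)
    manifest = {
        "version": __version__,
        "n_lambda": len(curves),
        "n_theta": len(np.asarray(theta_grid)),
        "n_distinct_regions": n_distinct,
        "labels": sorted(table["label"].unique()),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "region_map.csv", index=False, float_format=_CSV_FLOAT)
        curves.to_csv(
            outdir / "boundary_curves.csv", index=False, float_format=_CSV_FLOAT
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["region_table"] = table
    manifest["curves"] = curves
    return manifest


# ---------------------------------------------------------------------------
# ensemble sweep
# ---------------------------------------------------------------------------

def _tissue_seeds(master_seed: int, n_tissues: int) -> list[np.random.Generator]:
    return [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(master_seed).spawn(n_tissues)
    ]


def _sample_catalogue_entry(
    attractor: TissueAttractor,
    catalogue: dict[frozenset, int],
) -> np.ndarray:
    """Per-cell assignment into the tissue-global CA catalogue, growing
    the catalogue as new CAs appear."""
    cas = attractor.cell_attractors()
    out = np.empty(len(cas), dtype=np.intp)
    for i, ca in enumerate(cas):
        out[i] = catalogue.setdefault(ca, len(catalogue))
    return out


def run_sweep(config: SweepConfig, outdir: str | Path | None = None) -> dict:
    """Run the ensemble sweep; returns (and optionally writes) the
    metrics table, per-tissue taxonomy report and manifest.

    Per tissue: one random critical network, one random initial state
    shared by all its samples, three asocial reference runs (ON, OFF,
    SELF — exact for any point inside the corresponding region and
    independent of lambda and theta), then one coupled run per
    (lambda, theta) sample.  Samples that fail to reach an attractor
    within ``max_steps`` are flagged and excluded from the metrics.
    """
    lattice, params = config.lattice, config.field_params
    rngs = _tissue_seeds(config.seed, config.n_tissues)
    rows: list[dict] = []
    taxonomy: dict[str, dict] = {}
    timeouts: list[dict] = []
    profiles_frames: list[pd.DataFrame] = []

    theta_plan: list[tuple[float, np.ndarray, list[str]]] = []
    for lam in config.lambdas:
        thetas, labels = place_thetas(lam, params, lattice, n_mid=config.n_theta_mid)
        theta_plan.append((lam, thetas, labels))

    for tid, rng in enumerate(rngs):
        network = generate_rbn(config.n_regulatory, config.k, config.bias, rng)
        init = network.random_state(rng, n_cells=lattice.n_cells)
        catalogue: dict[frozenset, int] = {}

        refs: dict[str, np.ndarray] = {}
        ref_dists: dict[str, np.ndarray] = {}
        ref_attr = {
            mode: run_asocial_reference(
                network, lattice, params, init, mode, config.max_steps
            )
            for mode in ("on", "off", "self")
        }
        for mode, attr in ref_attr.items():
            refs[mode] = _sample_catalogue_entry(attr, catalogue)

        samples: list[dict] = []
        for lam, thetas, labels in theta_plan:
            for rank, (theta, label) in enumerate(zip(thetas, labels)):
                tissue = Tissue(network, lattice, params, lam, float(theta), init)
                attr = run_to_attractor(tissue, config.max_steps)
                if not attr.found:
                    timeouts.append(
                        {"tissue_id": tid, "lam": lam, "theta": float(theta)}
                    )
                    continue
                assignment = _sample_catalogue_entry(attr, catalogue)
                samples.append(
                    {
                        "tissue_id": tid,
                        "lam": lam,
                        "theta": float(theta),
                        "theta_rank": rank,
                        "region": label,
                        "assignment": assignment,
                        "transient": attr.transient,
                        "period": attr.period,
                    }
                )

        m_total = len(catalogue)
        ref_dists = {
            mode: ca_distribution(refs[mode], m_total) for mode in ("on", "off", "self")
        }
        catalogue_list = list(catalogue)  # index -> CA
        asocial_cas: set = set()
        for mode in ("on", "off", "self"):
            asocial_cas.update(catalogue_list[i] for i in np.unique(refs[mode]))
        social_cas: set = set()
        social_records: list[tuple[float, dict]] = []
        for s in samples:
            dist = ca_distribution(s["assignment"], m_total)
            s["b"] = b_metric(s["assignment"], refs["on"], refs["off"], refs["self"])
            s["dkl_hat"] = dkl_hat(
                dist, list(ref_dists.values()), epsilon=config.epsilon
            )
            s["entropy"] = tissue_entropy(dist)
            s["homogeneous"] = is_homogeneous(dist)
            s["M_sample"] = int(np.unique(s["assignment"]).size)
            expressed = {
                catalogue_list[i]: dist[i] for i in np.unique(s["assignment"])
            }
            if s["region"] in ASOCIAL:
                asocial_cas.update(expressed)
            else:
                social_cas.update(expressed)
                social_records.append((s["lam"], expressed))
            rows.append({k: v for k, v in s.items() if k != "assignment"})

        cat = CACatalogue(asocial_cas, social_cas)
        taxonomy[str(tid)] = {
            **cat.summary(),
            "M_total": m_total,
            "receptor_disconnected": is_receptor_disconnected(network),
        }
        stats = novel_lambda_stats(social_records, cat.novel)
        if not stats.empty:
            stats.insert(0, "tissue_id", tid)
            profiles_frames.append(stats)

    metrics = pd.DataFrame(rows)
    novel_profiles = (
        pd.concat(profiles_frames, ignore_index=True)
        if profiles_frames
        else pd.DataFrame(
            columns=["tissue_id", "lam", "novel_fraction", "novel_max_cell_fraction"]
        )
    )
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_samples": len(rows),
        "n_timeouts": len(timeouts),
        "timeouts": timeouts,
    }
    result = {
        "metrics": metrics,
        "taxonomy": taxonomy,
        "novel_profiles": novel_profiles,
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(outdir / "metrics.csv", index=False, float_format=_CSV_FLOAT)
        novel_profiles.to_csv(
            outdir / "novel_profiles.csv", index=False, float_format=_CSV_FLOAT
        )
        (outdir / "taxonomy.json").write_text(json.dumps(taxonomy, indent=2))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


# ---------------------------------------------------------------------------
# attractor-horizon ensemble
# ---------------------------------------------------------------------------

def run_attractor_horizon(
    n_tissues: int = 10,
    dims: tuple[int, int, int] = (16, 16, 16),
    seed: int = 0,
    max_steps: int = 2000,
    n_regulatory: int = 10,
    k: int = 3,
) -> pd.DataFrame:
    """First-recurrence times over an ensemble of critical tissues.

    Each tissue gets one random critical network and one random initial
    state, reused across six (lambda, theta) samples placed one per
    signaling region relative to the boundary curves.  Returns one row
    per sample with the transient, period and recurrence time (the step
    at which the global state first revisits a seen state); samples that
    fail within ``max_steps`` get ``found=False``.
    """
    config = SweepConfig(
        n_tissues=n_tissues,
        dims=dims,
        seed=seed,
        max_steps=max_steps,
        n_regulatory=n_regulatory,
        k=k,
    )
    lattice, params = config.lattice, config.field_params
    samples = six_region_samples(params, lattice)
    rows = []
    for tid, rng in enumerate(_tissue_seeds(seed, n_tissues)):
        network = generate_rbn(n_regulatory, k, config.bias, rng)
        init = network.random_state(rng, n_cells=lattice.n_cells)
        for label, lam, theta in samples:
            tissue = Tissue(network, lattice, params, lam, theta, init)
            attr = run_to_attractor(tissue, max_steps)
            rows.append(
                {
                    "tissue_id": tid,
                    "region": label,
                    "lam": lam,
                    "theta": theta,
                    "found": attr.found,
                    "transient": attr.transient,
                    "period": attr.period,
                    "recurrence_time": attr.recurrence_time if attr.found else None,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def three_node_toy_network() -> BooleanNetwork:
    """Deterministic 3-node toy: one regulatory NOT self-loop (period-2
    oscillator), signal copies the regulatory node, threshold receptor."""
    return BooleanNetwork(
        n_regulatory=1,
        k=1,
        wiring=np.array([[0], [0]]),  # regulatory reads itself; signal reads it
        truth_tables=np.array([[1, 0], [0, 1]], dtype=np.uint8),  # NOT; identity
    )


def make_fixtures(outdir: str | Path, n_rbn: int = 3, seed: int = 0) -> list[Path]:
    """Write the bundled network fixtures as plain-text network files:
    the 2-node constant-signal probe, the 3-node oscillator toy and
    ``n_rbn`` seeded 12-node critical networks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    fixtures: list[tuple[str, BooleanNetwork]] = [
        ("two_node_probe.bn", two_node_network()),
        ("three_node_toy.bn", three_node_toy_network()),
    ]
    p = critical_bias(3)
    for i, rng in enumerate(_tissue_seeds(seed, n_rbn)):
        fixtures.append((f"critical_rbn_{i}.bn", generate_rbn(10, 3, p, rng)))
    for name, net in fixtures:
        path = outdir / name
        write_network(net, path)
        paths.append(path)
    return paths
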