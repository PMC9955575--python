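"""Population-level metrics over cellular-attractor assignments.

For one tissue, every sample (a (lambda, theta) point) yields a per-cell
assignment into the tissue's global catalogue of unique cellular
attractors (CAs).  The metrics compare each sample against the three
asocial reference samples (ON, OFF, SELF regions):

- ``b``: fraction of cells occupying a *different* CA than in the most
  similar asocial reference (minimum normalized Hamming distance over
  the three references); 0 means communication left every cell's
  behavior unchanged.
- ``dkl_hat``: minimum symmetric Kullback–Leibler divergence between the
  sample's CA distribution and the three reference distributions, on
  epsilon-smoothed, renormalized vectors, natural log.
- ``entropy``: Shannon entropy (nats) of the CA distribution — tissue
  diversity; zero iff the sample is homogeneous (a single CA).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "hamming_change",
    "b_metric",
    "ca_distribution",
    "sym_kl",
    "dkl_hat",
    "tissue_entropy",
    "is_homogeneous",
    "lambda_profiles",
    "homogeneity_fraction",
]


def hamming_change(sample: np.ndarray, reference: np.ndarray) -> float:
    """Fraction of cells whose CA differs between two aligned assignments."""
    a = np.asarray(sample)
    b = np.asarray(reference)
    if a.shape != b.shape:
        raise ValueError(f"assignment lengths differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty assignments")
    return float(np.mean(a != b))


def b_metric(
    sample: np.ndarray,
    on_ref: np.ndarray,
    off_ref: np.ndarray,
    self_ref: np.ndarray,
) -> float:
    """Cellular-change metric: distance to the most similar asocial
    reference, ``min`` of the three normalized Hamming distances."""
    return min(
        hamming_change(sample, on_ref),
        hamming_change(sample, off_ref),
        hamming_change(sample, self_ref),
    )


def ca_distribution(assignment: np.ndarray, n_catalogue: int) -> np.ndarray:
    """Fraction of cells in each CA of the tissue's global catalogue.

    The vector always has length ``n_catalogue`` (the tissue's M across
    all samples), so distributions from different samples are aligned.
    """
    a = np.asarray(assignment)
    if a.size == 0:
        raise ValueError("empty assignment")
    if a.min() < 0 or a.max() >= n_catalogue:
        raise ValueError("assignment refers to CAs outside the catalogue")
    counts = np.bincount(a, minlength=n_catalogue).astype(float)
    return counts / a.size


def _smooth(p: np.ndarray, epsilon: float) -> np.ndarray:
    q = np.asarray(p, dtype=float) + epsilon
    return q / q.sum()


def sym_kl(dist_p: np.ndarray, dist_q: np.ndarray, epsilon: float = 1e-6) -> float:
    """Symmetric KL divergence ``D(P||Q) + D(Q||P)`` in nats.

    ``epsilon`` is added to every entry of both vectors (then each is
    renormalized) so zero fractions never hit the logarithm.
    """
    p = np.asarray(dist_p, dtype=float)
    q = np.asarray(dist_q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"distribution lengths differ: {p.shape} vs {q.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    ps, qs = _smooth(p, epsilon), _smooth(q, epsilon)
    log_ratio = np.log(ps) - np.log(qs)
    return float(np.sum((ps - qs) * log_ratio))


def dkl_hat(
    sample_dist: np.ndarray,
    reference_dists: Sequence[np.ndarray],
    epsilon: float = 1e-6,
) -> float:
    """Composition-change metric: minimum symmetric KL against the
    asocial reference distributions."""
    if not reference_dists:
        raise ValueError("need at least one reference distribution")
    return min(sym_kl(sample_dist, r, epsilon) for r in reference_dists)


def tissue_entropy(dist: np.ndarray) -> float:
    """Shannon entropy of a CA distribution in nats (0 log 0 = 0)."""
    d = np.asarray(dist, dtype=float)
    nz = d[d > 0]
    return float(-np.sum(nz * np.log(nz)) + 0.0)


def is_homogeneous(dist: np.ndarray) -> bool:
    """True iff exactly one CA carries all cells (entropy is zero)."""
    d = np.asarray(dist, dtype=float)
    return int(np.count_nonzero(d)) == 1


def lambda_profiles(
    records: pd.DataFrame,
    metric_cols: Iterable[str] = ("b", "dkl_hat"),
) -> pd.DataFrame:
    """Per-lambda normalized maxima of metrics, averaged over tissues.

    ``records`` must have columns ``tissue_id, lam, theta`` plus the
    metric columns.  For each tissue and lambda, the maximum of the
    metric over theta is taken and normalized by the tissue's overall
    maximum (a tissue whose metric is identically zero contributes a zero
    profile); profiles are then averaged across tissues.
    """
    metric_cols = list(metric_cols)
    if records.empty:
        raise ValueError("empty records")
    per_tissue = records.groupby(["tissue_id", "lam"])[metric_cols].max().reset_index()
    overall = records.groupby("tissue_id")[metric_cols].max()
    for col in metric_cols:
        denom = per_tissue["tissue_id"].map(overall[col])
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = per_tissue[col] / denom
        per_tissue[col] = norm.fillna(0.0)
        per_tissue.loc[denom.to_numpy() == 0, col] = 0.0
    return per_tissue.groupby("lam")[metric_cols].mean().reset_index()


def homogeneity_fraction(records: pd.DataFrame) -> pd.DataFrame:
    """Fraction of tissues homogeneous at each (lambda, theta) sample slot.

    Theta placement is curve-relative, so samples at the same lambda are
    aligned across tissues by their placement rank (``theta_rank``
    column if present, else exact theta).
    """
    key = "theta_rank" if "theta_rank" in records.columns else "theta"
    out = (
        records.groupby(["lam", key])["homogeneous"]
        .mean()
        .rename("homogeneous_fraction")
        .reset_index()
    )
    return out
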