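"""Batch self-organizing map on a toroidal hexagonal grid.

The SOM clusters binding sites by their binary TF co-binding profiles:
each grid neuron holds a codebook vector in TF space, sites map to their
best-matching neuron (Euclidean distance), and neighbouring neurons stay
similar because codebook updates are smoothed over the wrapped hexagonal
grid.  Several independent fits are run and the one with the smallest
mean site-to-codebook distance is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from loopscape.config import substream


def _hex_positions(nx: int, ny: int) -> np.ndarray:
    """Cartesian centers of an nx-by-ny hexagonal (offset rows) grid."""
    pos = np.zeros((nx * ny, 2))
    k = 0
    for j in range(ny):
        for i in range(nx):
            pos[k] = (i + 0.5 * (j % 2), j * np.sqrt(3) / 2)
            k += 1
    return pos


def _toroidal_grid_dist(nx: int, ny: int) -> np.ndarray:
    """Pairwise neuron distances with wraparound in both grid directions."""
    pos = _hex_positions(nx, ny)
    width, height = float(nx), ny * np.sqrt(3) / 2
    n = nx * ny
    d = np.zeros((n, n))
    shifts = [(sx * width, sy * height) for sx in (-1, 0, 1) for sy in (-1, 0, 1)]
    for a in range(n):
        delta = pos - pos[a]
        best = np.full(n, np.inf)
        for sx, sy in shifts:
            cand = np.hypot(delta[:, 0] + sx, delta[:, 1] + sy)
            best = np.minimum(best, cand)
        d[a] = best
    return d


@dataclass
class SOMModel:
    """Fitted map: codebook vectors, per-site assignments, fit quality."""

    grid_dims: tuple[int, int]
    codebook: np.ndarray                  # (n_neurons, n_features)
    assignment: np.ndarray                # best-matching neuron per site
    mean_distance: float                  # mean site-to-BMU Euclidean distance
    seed: int
    restart_metrics: list = field(default_factory=list)
    schedule: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.grid_dims[0] * self.grid_dims[1]


def _fit_once(X: np.ndarray, nx: int, ny: int, grid_d: np.ndarray,
              rng: np.random.Generator, n_epochs: int) -> tuple[np.ndarray, np.ndarray, float]:
    n, _ = X.shape
    m = nx * ny
    codebook = X[rng.choice(n, size=m, replace=False)].astype(float)
    # neighbourhood radius shrinks from half the grid diagonal to ~0.5
    r0 = max(grid_d.max() / 2.0, 1.0)
    radii = r0 * (0.5 / r0) ** (np.arange(n_epochs) / max(n_epochs - 1, 1))
    bmu = np.zeros(n, dtype=int)
    for r in radii:
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        h = np.exp(-(grid_d ** 2) / (2.0 * r * r))      # (m, m)
        w = h[bmu]                                       # (n, m) site->neuron weight
        denom = w.sum(axis=0)                            # (m,)
        num = w.T @ X                                    # (m, features)
        nzero = denom > 1e-12
        codebook[nzero] = num[nzero] / denom[nzero, None]
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    mean_dist = float(np.sqrt(d2[np.arange(n), bmu]).mean())
    return codebook, bmu, mean_dist


def som_fit(matrix: pd.DataFrame, grid_dims: tuple[int, int] = (4, 4),
            n_restarts: int = 10, seed: int = 0, n_epochs: int = 15) -> SOMModel:
    """Fit the SOM ``n_restarts`` times and keep the best-scoring model.

    ``matrix`` is the binary BindingMatrix (rows = binding sites, columns =
    TFs; an ``interacting`` column, if present, is ignored here).  The
    retained model minimizes the mean distance of rows to their
    best-matching codebook vector; per-restart metrics are kept so the
    choice is auditable.
    """
    feat = matrix.drop(columns=[c for c in ("interacting",) if c in matrix])
    X = feat.to_numpy(dtype=float)
    if len(X) == 0:
        raise ValueError("binding matrix is empty")
    nx, ny = grid_dims
    if nx * ny > len(X):
        raise ValueError(
            f"grid {nx}x{ny} has more neurons than rows ({len(X)}); use a smaller grid")
    grid_d = _toroidal_grid_dist(nx, ny)
    rng = substream(seed, "som")
    best = None
    metrics = []
    for _ in range(max(n_restarts, 1)):
        cb, bmu, md = _fit_once(X, nx, ny, grid_d, rng, n_epochs)
        metrics.append(md)
        if best is None or md < best[2]:
            best = (cb, bmu, md)
    cb, bmu, md = best
    return SOMModel(grid_dims=(nx, ny), codebook=cb, assignment=bmu,
                    mean_distance=md, seed=seed, restart_metrics=metrics,
                    schedule={"n_epochs": n_epochs, "radius_final": 0.5})


def som_interaction_enrichment(model: SOMModel, interacting: np.ndarray,
                               alpha: float = 0.01, min_fold: float = 2.0,
                               method: str = "fdr_bh") -> pd.DataFrame:
    """Neurons whose sites are enriched for interactions.

    Per neuron: Fisher's exact test on (in-neuron / out) x (interacting /
    not), multiple-testing correction across neurons (Benjamini–Hochberg
    by default, ``method='bonferroni'`` optional), keep q < alpha and fold
    enrichment > min_fold, where fold = neuron interacting fraction /
    global interacting fraction.
    """
    interacting = np.asarray(interacting, dtype=bool)
    if len(interacting) != len(model.assignment):
        raise ValueError("flags and model rows differ in length")
    n = len(interacting)
    global_frac = interacting.mean() if n else 0.0
    rows = []
    for neuron in range(model.n_neurons):
        inside = model.assignment == neuron
        a = int((inside & interacting).sum())
        b = int((inside & ~interacting).sum())
        c = int((~inside & interacting).sum())
        d = int((~inside & ~interacting).sum())
        p = float(stats.fisher_exact([[a, b], [c, d]])[1]) if inside.any() else 1.0
        frac = a / inside.sum() if inside.any() else 0.0
        fold = frac / global_frac if global_frac > 0 else 0.0
        rows.append((neuron, int(inside.sum()), a, frac, fold, p))
    out = pd.DataFrame(rows, columns=["neuron", "n_sites", "n_interacting",
                                      "interacting_fraction", "fold", "p"])
    out["q"] = multipletests(out["p"].to_numpy(), method=method)[1]
    out["enriched"] = (out["q"] < alpha) & (out["fold"] > min_fold)
    return out
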