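"""GMM-based free-energy landscapes over descriptor pairs.

A Gaussian mixture is fitted to 2D descriptor samples (EM capped at 20
iterations by default, component count selected over K = 2..12 by 3-fold
cross-validated log-likelihood), the density is evaluated on an 80×80 grid
and converted to free energy F = -kT ln p (minimum shifted to zero), and
core states are extracted as gradient-ascent basins of the density grid.
The landscape only pictures the neighbourhood of the sampled local minima;
cells whose density falls below a floor are masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

DENSITY_FLOOR_RATIO = 1e-6      # mask cells below this fraction of peak density
BASIN_MERGE_RATIO = 0.05        # basins peaking below 5% of the global peak merge


def fit_density(samples: np.ndarray, k_min: int = 2, k_max: int = 12,
                max_iter: int = 20, seed: int = 0) -> GaussianMixture:
    """Fit a 2D Gaussian mixture with cross-validated component count.

    For each K in [k_min, k_max] an EM fit (seeded k-means++ initialisation,
    ``max_iter`` iterations, covariance eigenvalues floored at 1e-6) is scored
    by mean held-out log-likelihood under 3-fold CV; the best K is refitted on
    all samples and returned.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("samples must have shape (n, 2)")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    n = len(samples)
    if n < 50:
        raise ValueError(f"need >= 50 samples, got {n}")
    # canonical ordering makes the fit invariant to sample permutation
    samples = samples[np.lexsort((samples[:, 1], samples[:, 0]))]

    def gmm(k: int) -> GaussianMixture:
        return GaussianMixture(n_components=k, max_iter=max_iter,
                               init_params="k-means++", random_state=seed,
                               reg_covar=1e-6, n_init=1)

    kf = KFold(n_splits=3, shuffle=True, random_state=seed)
    best_k, best_score = k_min, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EM may hit max_iter without tight tol
        for k in range(k_min, k_max + 1):
            scores = []
            for train, test in kf.split(samples):
                model = gmm(k).fit(samples[train])
                scores.append(model.score(samples[test]))
            mean_score = float(np.mean(scores))
            if mean_score > best_score:
                best_k, best_score = k, mean_score
        final = gmm(best_k).fit(samples)
    return final


@dataclass
class Landscape:
    """2D free-energy grid (kT) with the fitted mixture and core-state labels."""

    metric_x: str
    metric_y: str
    x_centers: np.ndarray            # (grid,)
    y_centers: np.ndarray
    density: np.ndarray              # (grid, grid), row = x index
    free_energy: np.ndarray          # kT, min-shifted; NaN where masked
    mixture: GaussianMixture
    kT: float = 1.0
    state_labels: np.ndarray | None = None    # 0 = unassigned
    populations: dict = field(default_factory=dict)

    @property
    def cell_area(self) -> float:
        return float((self.x_centers[1] - self.x_centers[0]) *
                     (self.y_centers[1] - self.y_centers[0]))

    def plot(self, ax=None, cmap: str = "viridis", max_kt: float | None = None):
        """Free-energy heatmap with core-state minima marked; returns the axes."""
        import matplotlib.pyplot as plt
        if ax is None:
            _fig, ax = plt.subplots(figsize=(5, 4))
        fe = self.free_energy.T        # imshow rows = y
        im = ax.imshow(fe, origin="lower", aspect="auto", cmap=cmap,
                       vmax=max_kt,
                       extent=(self.x_centers[0], self.x_centers[-1],
                               self.y_centers[0], self.y_centers[-1]))
        if self.state_labels is not None:
            for lab in self.populations:
                cells = np.argwhere(self.state_labels == lab)
                i, j = min(cells, key=lambda c: self.free_energy[c[0], c[1]])
                ax.plot(self.x_centers[i], self.y_centers[j], "w+", ms=8)
        ax.set_xlabel(self.metric_x)
        ax.set_ylabel(self.metric_y)
        ax.figure.colorbar(im, ax=ax, label=f"F ({'kT' if self.kT == 1 else 'energy'})")
        return ax

    def to_table(self) -> pd.DataFrame:
        xi, yi = np.meshgrid(np.arange(len(self.x_centers)),
                             np.arange(len(self.y_centers)), indexing="ij")
        labels = self.state_labels if self.state_labels is not None \
            else np.zeros_like(self.density, dtype=int)
        return pd.DataFrame({
            "x": self.x_centers[xi.ravel()], "y": self.y_centers[yi.ravel()],
            "free_energy_kT": self.free_energy.ravel(),
            "state": labels.ravel(),
        })


def free_energy_grid(mixture: GaussianMixture, ranges, grid: int = 80,
                     kT: float = 1.0, metric_x: str = "x",
                     metric_y: str = "y") -> Landscape:
    """Evaluate F(cell) = -kT ln p(cell centre), shifted so min F = 0.

    ``ranges`` = ((x_lo, x_hi), (y_lo, y_hi)).  Cells with density below
    1e-6 of the peak are masked (NaN free energy).
    """
    (x_lo, x_hi), (y_lo, y_hi) = ranges
    x_edges = np.linspace(x_lo, x_hi, grid + 1)
    y_edges = np.linspace(y_lo, y_hi, grid + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    logp = mixture.score_samples(pts).reshape(grid, grid)
    density = np.exp(logp)
    mask = density < DENSITY_FLOOR_RATIO * density.max()
    fe = -kT * (logp - logp.max())      # = -kT ln(p / p_max), so min is 0
    fe[mask] = np.nan
    return Landscape(metric_x, metric_y, xc, yc, density, fe, mixture, kT)


def density_quadrature(mixture: GaussianMixture, ranges, grid: int = 400) -> float:
    """Quadrature of the mixture density over the given window (≈1 when the
    window covers the support)."""
    (x_lo, x_hi), (y_lo, y_hi) = ranges
    xc = np.linspace(x_lo, x_hi, grid)
    yc = np.linspace(y_lo, y_hi, grid)
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    p = np.exp(mixture.score_samples(np.column_stack([xx.ravel(), yy.ravel()])))
    da = (xc[1] - xc[0]) * (yc[1] - yc[0])
    return float(p.sum() * da)


def find_core_states(landscape: Landscape) -> Landscape:
    """Label density basins by steepest-ascent on the grid.

    Every unmasked cell follows its highest-density 8-neighbour uphill to a
    local maximum; basins whose peak density is below 5% of the global peak
    are merged into the neighbouring basin they drain closest to.  Populations
    are the basin sums of density normalised over the unmasked region.
    States are numbered 1..K by decreasing population; masked cells keep 0.
    """
    dens = landscape.density
    grid_x, grid_y = dens.shape
    masked = dens < DENSITY_FLOOR_RATIO * dens.max() if dens.max() > 0 else \
        np.ones_like(dens, dtype=bool)
    labels = np.zeros(dens.shape, dtype=int)
    if masked.all():
        landscape.state_labels = labels
        landscape.populations = {}
        return landscape

    order = np.argsort(dens, axis=None)[::-1]
    neighbours = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    peaks: list[float] = []        # peak density per basin (1-based labels)
    for flat in order:
        i, j = divmod(int(flat), grid_y)
        if masked[i, j]:
            continue
        # cells are visited by decreasing density, so every higher neighbour
        # is already labelled; near-ties (symmetric peaks discretised onto
        # the grid) attach instead of seeding spurious basins
        best_lab, best_d = 0, -np.inf
        for di, dj in neighbours:
            ni, nj = i + di, j + dj
            if 0 <= ni < grid_x and 0 <= nj < grid_y and labels[ni, nj] > 0 \
                    and dens[ni, nj] >= dens[i, j] * (1.0 - 1e-9) \
                    and dens[ni, nj] > best_d:
                best_d = dens[ni, nj]
                best_lab = labels[ni, nj]
        if best_lab == 0:
            peaks.append(float(dens[i, j]))
            best_lab = len(peaks)
        labels[i, j] = best_lab

    # merge weak basins into the strongest adjacent basin
    peak_max = max(peaks)
    weak = {k + 1 for k, p in enumerate(peaks) if p < BASIN_MERGE_RATIO * peak_max}
    for lab in sorted(weak, key=lambda l: peaks[l - 1]):
        cells = np.argwhere(labels == lab)
        target, target_peak = 0, -1.0
        for i, j in cells:
            for di, dj in neighbours:
                ni, nj = i + di, j + dj
                if 0 <= ni < grid_x and 0 <= nj < grid_y:
                    l2 = labels[ni, nj]
                    if l2 > 0 and l2 != lab and l2 not in weak \
                            and peaks[l2 - 1] > target_peak:
                        target, target_peak = l2, peaks[l2 - 1]
        if target == 0:   # isolated weak basin: absorb into the global peak basin
            target = int(np.argmax(peaks)) + 1
        labels[labels == lab] = target

    kept = sorted(set(labels.ravel()) - {0})
    total = dens[~masked].sum()
    pops = {lab: float(dens[labels == lab].sum() / total) for lab in kept}
    # renumber by decreasing population
    ranking = sorted(pops, key=pops.get, reverse=True)
    remap = {old: new + 1 for new, old in enumerate(ranking)}
    relabeled = np.zeros_like(labels)
    for old, new in remap.items():
        relabeled[labels == old] = new
    landscape.state_labels = relabeled
    landscape.populations = {remap[k]: v for k, v in pops.items()}
    return landscape


@dataclass
class ConvergenceProfile:
    block_means: np.ndarray
    block_sds: np.ndarray
    cumulative_mean: np.ndarray
    converged: bool

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"block": np.arange(1, len(self.block_means) + 1),
                             "mean": self.block_means, "sd": self.block_sds})


def convergence_profile(series: np.ndarray, n_blocks: int = 5) -> ConvergenceProfile:
    """Block-average convergence check for one descriptor series.

    The series is split into equal contiguous blocks; it is flagged converged
    when the last two block means differ by less than one pooled block sd.
    """
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    block_len = len(series) // n_blocks
    if block_len < 2:
        raise ValueError(f"blocks of {block_len} < 2 samples; series too short")
    trimmed = series[:block_len * n_blocks].reshape(n_blocks, block_len)
    means = trimmed.mean(axis=1)
    sds = trimmed.std(axis=1, ddof=1)
    cum = np.cumsum(series) / np.arange(1, len(series) + 1)
    pooled = float(np.sqrt(0.5 * (sds[-1] ** 2 + sds[-2] ** 2)))
    converged = bool(abs(means[-1] - means[-2]) < pooled) if pooled > 0 \
        else bool(means[-1] == means[-2])
    return ConvergenceProfile(means, sds, cum, converged)
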