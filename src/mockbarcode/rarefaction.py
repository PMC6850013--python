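"""Richness rarefaction by repeated subsampling without replacement, plus
the consecutive-slope asymptote criterion."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DEPTH_GRID",
    "RarefactionConfig",
    "RarefactionCurve",
    "subsample_richness",
    "accumulation_curve",
    "asymptote_depth",
]

#: 10^2, 10^3, 10^3.5, 10^4, 10^4.5, 10^5, 10^5.5, 10^6 (rounded)
DEFAULT_DEPTH_GRID = (100, 1_000, 3_162, 10_000, 31_623,
                      100_000, 316_228, 1_000_000)


@dataclass(frozen=True)
class RarefactionConfig:
    depth_grid: tuple[int, ...] = DEFAULT_DEPTH_GRID
    n_replicates: int = 10_000
    slope_threshold: float = 0.01
    slope_axis: str = "linear"
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = tuple(self.depth_grid)
        if any(d <= 0 for d in grid) or any(
                b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("depth_grid must be strictly increasing positive")
        if self.slope_threshold <= 0:
            raise ValueError("slope_threshold must be > 0")
        if self.slope_axis not in ("linear", "log10"):
            raise ValueError("slope_axis must be 'linear' or 'log10'")


@dataclass
class RarefactionCurve:
    """Mean/sd richness per evaluated depth, as a tidy frame."""

    table: pd.DataFrame  # columns: depth, mean_richness, sd_richness

    @property
    def depths(self) -> np.ndarray:
        return self.table["depth"].to_numpy()

    @property
    def means(self) -> np.ndarray:
        return self.table["mean_richness"].to_numpy()

    def to_tsv(self, path, config: "RarefactionConfig | None" = None) -> None:
        out = self.table.copy()
        slopes = _slopes(self, (config or RarefactionConfig()).slope_axis)
        out["slope_to_next"] = list(slopes) + [np.nan]
        out.to_csv(path, sep="\t", index=False)


def subsample_richness(
    counts, depth: int, n_replicates: int = 10_000,
    seed: int | None = None, rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean and sd of richness over random subsamples of size ``depth``.

    Each replicate draws ``depth`` reads without replacement from the count
    vector (multivariate hypergeometric); richness is the number of rows
    with at least one draw. If ``depth`` exceeds the total count, the full
    pool is used and a warning issued (richness is then exact, sd 0).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("all counts are zero")
    if depth > total:
        warnings.warn(
            f"requested depth {depth} exceeds total count {total}; "
            "returning richness at full depth", stacklevel=2)
        depth = total
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(counts, depth, size=n_replicates)
    richness = (draws > 0).sum(axis=1)
    return float(richness.mean()), float(richness.std(ddof=1))


def accumulation_curve(counts, config: RarefactionConfig | None = None) -> RarefactionCurve:
    """Rarefaction curve over every grid depth not exceeding the total count
    (the total itself is appended as a final exact point if the grid
    overshoots)."""
    config = config or RarefactionConfig()
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("all counts are zero")
    rng = np.random.default_rng(config.seed)
    rows = []
    depths = [d for d in config.depth_grid if d <= total]
    if not depths or depths[-1] < total and len(depths) < len(config.depth_grid):
        depths = depths + [total]
    for depth in depths:
        mean, sd = subsample_richness(counts, depth, config.n_replicates, rng=rng)
        rows.append({"depth": depth, "mean_richness": mean, "sd_richness": sd})
    return RarefactionCurve(pd.DataFrame(rows))


def _slopes(curve: RarefactionCurve, slope_axis: str) -> np.ndarray:
    depths = curve.depths.astype(float)
    x = np.log10(depths) if slope_axis == "log10" else depths
    return np.diff(curve.means) / np.diff(x)


def asymptote_depth(
    curve: RarefactionCurve, config: RarefactionConfig | None = None,
) -> int | None:
    """First depth at which the curve is judged asymptotic.

    Returns the left endpoint of the first consecutive depth pair whose
    slope (change in mean richness per unit of the configured axis) is
    strictly below the threshold, or None if no pair qualifies.
    """
    config = config or RarefactionConfig()
    if len(curve.table) < 2:
        raise ValueError("need at least two grid points")
    slopes = _slopes(curve, config.slope_axis)
    below = np.flatnonzero(slopes < config.slope_threshold)
    if below.size == 0:
        return None
    return int(curve.depths[below[0]])
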