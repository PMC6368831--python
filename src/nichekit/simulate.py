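"""Virtual-species simulation: environments, truth, occurrences, layouts.

The simulator builds spatially autocorrelated environmental layers
(Gaussian-smoothed white noise rescaled to [0, 1]), a known true suitability
surface (logistic in linear + quadratic terms of the layers, giving smooth
unimodal responses), presence cells drawn without replacement with
probability proportional to suitability, and the train/test/independent
splits and on-disk project layout the calibration pipeline expects.
Transfer scenarios are additive shifts of the calibration layers, so the
expected amount of strict extrapolation is controlled by the shift size.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import EnvStack, Grid, OccurrenceSet, ProjectLayout, write_grid, write_occurrences

__all__ = [
    "VirtualSpeciesConfig",
    "generate_env",
    "true_suitability",
    "sample_occurrences",
    "simulate_project",
]


@dataclass
class VirtualSpeciesConfig:
    """Parameters of the simulated species and its landscape.

    Default landscape: a 64 x 64 grid of 3 layers smoothed with a 5-cell
    Gaussian radius.  The species has a sharp unimodal niche on the first
    two layers (optima at 0.625 and 0.4 of their ranges, the third layer is
    uninformative), peak suitability ~0.7 falling to ~0 at the range edges,
    with 200 presence cells, a 75/25 train/test split, and 30 independent
    records.
    """

    seed: int
    rows: int = 64
    cols: int = 64
    n_layers: int = 3
    smoothness: float = 5.0
    beta_linear: tuple[float, ...] = (50.0, 16.0, 0.0)
    beta_quadratic: tuple[float, ...] = (-40.0, -20.0, 0.0)
    intercept: float = -18.0
    n_presence: int = 200
    train_fraction: float = 0.75
    n_independent: int = 30
    g_offsets: dict = field(default_factory=lambda: {"current": 0.0, "future": 0.25})
    detection_noise: float = 0.0  # fraction of presences moved to random cells
    cellsize: float = 0.05
    origin: tuple[float, float] = (-10.0, 10.0)  # upper-left (lon, lat)

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_presence < 10:
            raise ValueError("n_presence must be >= 10")
        if len(self.beta_linear) != self.n_layers or len(self.beta_quadratic) != self.n_layers:
            raise ValueError("coefficient vectors must have one entry per layer")


def _transform(config: VirtualSpeciesConfig):
    x0, y0 = config.origin
    return (x0, config.cellsize, 0.0, y0, 0.0, -config.cellsize)


def generate_env(config: VirtualSpeciesConfig) -> EnvStack:
    """Seeded, spatially autocorrelated layers rescaled to [0, 1]."""
    rng = np.random.default_rng(config.seed)
    transform = _transform(config)
    layers, names = [], []
    for i in range(config.n_layers):
        noise = rng.standard_normal((config.rows, config.cols))
        if config.smoothness > 0:
            noise = gaussian_filter(noise, sigma=config.smoothness, mode="reflect")
        lo, hi = noise.min(), noise.max()
        vals = (noise - lo) / (hi - lo)
        layers.append(
            Grid(vals, np.zeros_like(vals, dtype=bool), transform, crs_label="synthetic")
        )
        names.append(f"env_{i + 1}")
    return EnvStack(layers=layers, names=names)


def true_suitability(stack: EnvStack, config: VirtualSpeciesConfig) -> Grid:
    """logistic(intercept + beta_l . x + beta_q . x^2) per cell, in (0, 1)."""
    eta = np.full(stack.shape, config.intercept, dtype=float)
    for g, bl, bq in zip(stack.layers, config.beta_linear, config.beta_quadratic):
        eta += bl * g.values + bq * g.values**2
    suit = expit(eta)
    suit = np.where(stack.mask, 0.0, suit)
    return stack.layers[0].copy_with(suit, stack.mask.copy())


def _draw_cells(
    suitability: Grid, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    valid = np.flatnonzero(~suitability.nodata_mask.ravel())
    weights = suitability.values.ravel()[valid]
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability sums to zero; nothing to sample")
    if n > valid.size:
        raise ValueError(f"requested {n} presences but only {valid.size} cells")
    chosen = rng.choice(valid, size=n, replace=False, p=weights / total)
    rows, cols = np.divmod(chosen, suitability.shape[1])
    return rows, cols


def sample_occurrences(
    suitability: Grid,
    config: VirtualSpeciesConfig,
    species: str = "virtualis exempli",
) -> dict[str, OccurrenceSet]:
    """Draw presence cells proportional to suitability and split them.

    Returns occurrence sets for roles joint/train/test/independent, with
    coordinates at cell centers.  The independent set is drawn separately
    from the same distribution.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows, cols = _draw_cells(suitability, config.n_presence, rng)
    if config.detection_noise > 0:
        n_flip = int(round(config.detection_noise * config.n_presence))
        if n_flip:
            valid = np.flatnonzero(~suitability.nodata_mask.ravel())
            repl = rng.choice(valid, size=n_flip, replace=False)
            which = rng.choice(config.n_presence, size=n_flip, replace=False)
            rows[which], cols[which] = np.divmod(repl, suitability.shape[1])
    lon, lat = suitability.cell_centers(rows, cols)
    records = np.column_stack([lon, lat])
    perm = rng.permutation(config.n_presence)
    n_train = int(round(config.train_fraction * config.n_presence))
    joint = OccurrenceSet(species, records, "joint")
    train = OccurrenceSet(species, records[perm[:n_train]], "train")
    test = OccurrenceSet(species, records[perm[n_train:]], "test")
    irows, icols = _draw_cells(suitability, config.n_independent, rng)
    ilon, ilat = suitability.cell_centers(irows, icols)
    independent = OccurrenceSet(species, np.column_stack([ilon, ilat]), "independent")
    return {"joint": joint, "train": train, "test": test, "independent": independent}


def simulate_project(
    root, config: VirtualSpeciesConfig, set_ids: tuple[str, ...] = ("Set_1",)
) -> tuple[ProjectLayout, EnvStack, Grid, dict[str, OccurrenceSet]]:
    """Write a complete starting project layout for the pipeline.

    One environmental stack is shared across the requested predictor sets
    (sets can later be subset by the user); each set gets every configured
    G scenario as an additive shift of the M layers.
    """
    root = Path(root)
    stack = generate_env(config)
    suit = true_suitability(stack, config)
    occs = sample_occurrences(suit, config)
    layout = ProjectLayout(root)
    write_occurrences(occs["joint"], layout.joint_csv)
    write_occurrences(occs["train"], layout.train_csv)
    write_occurrences(occs["test"], layout.test_csv)
    write_occurrences(occs["independent"], layout.independent_csv)
    for set_id in set_ids:
        m_dir = layout.m_set_dir(set_id)
        for name, grid in zip(stack.names, stack.layers):
            write_grid(grid, m_dir / f"{name}.asc")
        for scen, offset in config.g_offsets.items():
            g_dir = layout.g_scenario_dir(set_id, scen)
            for name, grid in zip(stack.names, stack.layers):
                shifted = grid.copy_with(grid.values + offset)
                write_grid(shifted, g_dir / f"{name}.asc")
    write_grid(suit, root / "true_suitability.asc")
    return layout, stack, suit, occs
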