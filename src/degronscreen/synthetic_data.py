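"""Synthetic inputs with the statistical structure the screen analysis assumes.

Everything downstream — plate scoring, responsiveness calls, decay fits,
GO-slim recovery, montages — can be exercised on data from this module with
a known planted truth.  Colony sizes are multiplicative log-normal around a
base size (sizes are positive, skewed areas); lethal strains draw their
induced size around ``effect_size`` times the uninduced mean; a positional
edge boost multiplies the outermost ring in *both* conditions so that the
ratio-based score can be shown to cancel it.  Per-cell fluorescence is an
additive autofluorescence background plus a log-normal GFP signal that is
multiplied by a depletion factor after induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fluorescence_screen import COND_T0, COND_T24H, CHANNEL_GFP, CellPopulation
from .growth_screen import PlateGrid

__all__ = [
    "ScreenSimConfig",
    "CellSimConfig",
    "gen_plate_pair",
    "gen_cell_population",
    "gen_timecourse",
    "gen_annotation_table",
    "gen_cell_image",
]


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of a simulated induced/uninduced plate pair.

    Defaults emulate a 1,536-format screen: a 32x48 grid, colony sizes with
    ~10% CV, 10% planted lethal strains whose induced colonies are ~5% of
    their uninduced size, and mildly boosted edge growth.
    """

    layout: tuple[int, int] = (32, 48)
    n_strains: int = 1000
    lethal_fraction: float = 0.1
    effect_size: float = 0.05
    noise_cv: float = 0.1
    edge_boost: float = 1.2
    base_size: float = 300.0
    media: str = "rich"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lethal_fraction <= 1.0):
            raise ValueError("lethal_fraction must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")


@dataclass(frozen=True)
class CellSimConfig:
    """Parameters of a simulated per-cell GFP population.

    The signal is log-normal (location ``log_mean``, scale ``log_sd`` on the
    log scale) on top of an additive near-Gaussian autofluorescence floor;
    after induction the signal component is multiplied by
    ``depletion_factor``.
    """

    n_cells: int = 200
    log_mean: float = float(np.log(1000.0))
    log_sd: float = 0.25
    autofluorescence_mean: float = 100.0
    autofluorescence_sd: float = 10.0
    depletion_factor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0.0 <= self.depletion_factor <= 1.0):
            raise ValueError("depletion_factor must be in [0, 1]")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _edge_mask(shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[0, :] = mask[-1, :] = True
    mask[:, 0] = mask[:, -1] = True
    return mask


def gen_plate_pair(
    config: ScreenSimConfig, replicate: int = 1
) -> tuple[PlateGrid, PlateGrid, pd.Series]:
    """Simulate one induced/uninduced plate pair with planted lethal strains.

    Strains fill the grid row-major.  Returns the two plates plus the planted
    truth (a boolean Series indexed by strain id, True = lethal).  The lethal
    assignment depends only on ``config.seed`` while the colony noise also
    mixes in ``replicate``, so replicate plates of the same screen share
    their planted truth but not their noise.
    """
    nrow, ncol = config.layout
    if config.n_strains > nrow * ncol:
        raise ValueError(
            f"layout {config.layout} holds {nrow * ncol} colonies, "
            f"cannot place {config.n_strains} strains"
        )
    rng_truth = np.random.default_rng(config.seed)
    rng_noise = np.random.default_rng(np.random.SeedSequence([config.seed, replicate]))

    width = len(str(config.n_strains))
    strain_ids = [f"STR{i + 1:0{width}d}" for i in range(config.n_strains)]
    n_lethal = int(round(config.lethal_fraction * config.n_strains))
    lethal_idx = rng_truth.choice(config.n_strains, size=n_lethal, replace=False)
    lethal = np.zeros(config.n_strains, dtype=bool)
    lethal[lethal_idx] = True

    noise_u = _lognormal_noise(rng_noise, config.noise_cv, config.n_strains)
    noise_i = _lognormal_noise(rng_noise, config.noise_cv, config.n_strains)
    sizes_u = config.base_size * noise_u
    sizes_i = config.base_size * noise_i
    sizes_i[lethal] *= config.effect_size  # induced mean = effect_size x uninduced mean

    grid_u = np.zeros((nrow, ncol))
    grid_i = np.zeros((nrow, ncol))
    strain_map: dict[tuple[int, int], str] = {}
    for idx, sid in enumerate(strain_ids):
        pos = (idx // ncol, idx % ncol)
        strain_map[pos] = sid
        grid_u[pos] = sizes_u[idx]
        grid_i[pos] = sizes_i[idx]
    edge = _edge_mask((nrow, ncol))
    grid_u[edge] *= config.edge_boost  # same positional factor in both conditions
    grid_i[edge] *= config.edge_boost

    base = f"SIMPLATE-s{config.seed}"
    uninduced = PlateGrid(base, config.media, False, replicate, grid_u, dict(strain_map))
    induced = PlateGrid(base, config.media, True, replicate, grid_i, dict(strain_map))
    truth = pd.Series(lethal, index=strain_ids, name="lethal")
    return induced, uninduced, truth


def gen_cell_population(
    config: CellSimConfig,
    induced: bool,
    strain_id: str = "SIM",
    channel: str = CHANNEL_GFP,
) -> CellPopulation:
    """Simulate per-cell mean intensities for one strain and condition.

    intensity = autofluorescence draw + log-normal signal draw, the signal
    multiplied by ``depletion_factor`` when induced.  Induced and uninduced
    populations are independent samples (different cells are imaged) but
    each is deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(induced)]))
    af = rng.normal(config.autofluorescence_mean, config.autofluorescence_sd, config.n_cells)
    af = np.clip(af, 1e-9, None)  # intensities are camera counts, strictly positive
    signal = rng.lognormal(config.log_mean, config.log_sd, config.n_cells)
    if induced:
        signal = signal * config.depletion_factor
    pop = CellPopulation(
        strain_id=strain_id,
        channel=channel,
        condition=COND_T24H if induced else COND_T0,
        intensities=af + signal,
    )
    pop.summarize()
    return pop


def gen_timecourse(
    t50: float,
    plateau: float,
    timepoints: Sequence[float],
    noise_cv: float,
    n_rep: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate replicate degradation time courses.

    The noiseless curve is y(t) = plateau + (1 - plateau) * 2^(-t / t50),
    i.e. a one-phase decay starting at 1 with half-life ``t50`` toward
    ``plateau``; every observation is multiplied by unit-mean log-normal
    noise with CV ``noise_cv``.  Returns (times, values) with values shaped
    (n_rep, n_timepoints).
    """
    if t50 <= 0:
        raise ValueError("t50 must be positive")
    if not (0.0 <= plateau < 1.0):
        raise ValueError("plateau must be in [0, 1)")
    times = np.asarray(timepoints, dtype=float)
    if 0.0 not in times:
        raise ValueError("timepoints must include 0")
    rng = np.random.default_rng(seed)
    clean = plateau + (1.0 - plateau) * np.power(2.0, -times / t50)
    values = clean[None, :] * _lognormal_noise(rng, noise_cv, (n_rep, times.size))
    return times, values


def gen_annotation_table(
    n_genes: int,
    terms: Sequence[tuple[str, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a gene -> GO-slim term table with fixed term sizes.

    Each term is assigned to exactly its stated number of genes, sampled
    without replacement from ``n_genes`` synthetic gene ids.  Returns the
    two-column (gene_id, term_id) frame consumed by the enrichment module.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = np.array([f"G{i + 1:0{width}d}" for i in range(n_genes)])
    rows: list[tuple[str, str]] = []
    for term_id, size in terms:
        if size > n_genes:
            raise ValueError(f"term {term_id} size {size} exceeds n_genes={n_genes}")
        chosen = rng.choice(n_genes, size=size, replace=False)
        rows.extend((genes[i], term_id) for i in sorted(chosen))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def gen_cell_image(
    n_cells: int,
    image_size: tuple[int, int] = (512, 512),
    cell_radius: int = 10,
    intensity: int = 10000,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a single-channel image of non-overlapping disk "cells".

    Cells are uniform disks of the given intensity on a zero background,
    placed fully inside the frame by rejection sampling.  Returns the 16-bit
    image and a centroid table (cell_id, x, y, intensity) consumable by the
    montage module.  Raises if ``n_cells`` cannot be placed without overlap
    within ``max_tries`` attempts per cell.
    """
    h, w = image_size
    rng = np.random.default_rng(seed)
    img = np.zeros((h, w), dtype=np.uint16)
    centers: list[tuple[int, int]] = []
    r = int(cell_radius)
    min_sep2 = (2 * r + 1) ** 2
    for _ in range(n_cells):
        for attempt in range(max_tries):
            cy = int(rng.integers(r, h - r))
            cx = int(rng.integers(r, w - r))
            if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep2 for y, x in centers):
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells of radius {r} "
                f"in a {image_size} frame after {max_tries} tries"
            )
    yy, xx = np.ogrid[:h, :w]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = intensity
    table = pd.DataFrame(
        {
            "cell_id": [f"cell{i + 1:04d}" for i in range(len(centers))],
            "x": [cx for _, cx in centers],
            "y": [cy for cy, _ in centers],
            "intensity": intensity,
        }
    )
    return img, table
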