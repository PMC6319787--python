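"""Synthetic fibrotic-scar fields and seeded obstacle textures.

In the imaging-based original, the normalized late-gadolinium signal
intensity is interpreted as a local fibrosis percentage: above 41 % the
tissue behaves as inexcitable necrotic core, below that as a border zone
whose fibrosis percentage gives each grid node its probability of being an
uncoupled unexcitable obstacle.  Here those fields are generated
synthetically:

* a circular scar with a radially linear fibrosis gradient (e.g. 50 % at the
  center falling to 0 % at the rim, diameter 6.4 cm),
* uniform-fibrosis disks for phase-diagram experiments,
* control geometries: no scar at all, and a purely necrotic scar (solid
  obstacle disk with no partially fibrotic border).

Textures are drawn by comparing one shared per-node uniform field against
f/100, so a given seed yields the same texture across runs and raising the
fibrosis map pointwise can only add obstacles (monotone coupling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import hashlib

import numpy as np

from .tissue import DX_CM, TissueGrid

__all__ = ["ScarSpec", "FibrosisMap", "ObstacleTexture",
           "make_fibrosis_map", "sample_texture", "make_controls",
           "make_scar_grid"]


@dataclass(frozen=True)
class ScarSpec:
    """Geometry and fibrosis profile of one circular scar.

    ``profile`` is ``"radial_linear"`` (level at the center falling linearly
    to 0 at the rim) or ``"uniform"`` (constant level inside the disk).
    ``center`` is in grid coordinates (row, col); ``diameter`` in cm;
    ``level`` in percent.
    """

    center: Tuple[int, int]
    diameter: float = 6.4
    profile: str = "radial_linear"
    level: float = 50.0

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("scar diameter must be positive")
        if not 0.0 <= self.level <= 100.0:
            raise ValueError("fibrosis level must lie in [0, 100] percent")
        if self.profile not in ("radial_linear", "uniform"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def radius_cm(self) -> float:
        return self.diameter / 2.0


@dataclass
class FibrosisMap:
    """Scalar fibrosis-percentage field on the grid (percent, in [0, 100])."""

    values: np.ndarray
    dx: float = DX_CM

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("fibrosis percentages must lie in [0, 100]")

    @property
    def shape(self):
        return self.values.shape

    def normalized_si(self) -> np.ndarray:
        """Equivalent normalized signal-intensity field (f / 100)."""
        return self.values / 100.0

    def hash(self) -> str:
        return hashlib.sha1(np.ascontiguousarray(self.values).tobytes()).hexdigest()[:12]


@dataclass
class ObstacleTexture:
    """One seeded Bernoulli realization of a fibrosis map."""

    mask: np.ndarray
    seed: int
    map_hash: str

    @property
    def obstacle_fraction(self) -> float:
        return float(self.mask.mean())


def _radius_grid(shape, center, dx) -> np.ndarray:
    rows, cols = shape
    r0, c0 = center
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.hypot(rr - r0, cc - c0) * dx


def make_fibrosis_map(spec: ScarSpec, shape: Tuple[int, int],
                      dx: float = DX_CM) -> FibrosisMap:
    """Fibrosis-percentage field for one scar on a grid of ``shape``.

    Distances are physical (node index times ``dx``) from the scar center;
    nodes at or beyond the rim get 0 %.  A scar that does not fit inside the
    domain is rejected.
    """
    r0, c0 = spec.center
    rad_nodes = spec.radius_cm / dx
    rows, cols = shape
    if (r0 - rad_nodes < -0.5 or r0 + rad_nodes > rows - 0.5
            or c0 - rad_nodes < -0.5 or c0 + rad_nodes > cols - 0.5):
        raise ValueError(
            f"scar of diameter {spec.diameter} cm at {spec.center} exceeds the "
            f"{rows}x{cols} domain")
    r = _radius_grid(shape, spec.center, dx)
    inside = r < spec.radius_cm
    f = np.zeros(shape, dtype=float)
    if spec.profile == "radial_linear":
        f[inside] = spec.level * (1.0 - r[inside] / spec.radius_cm)
    else:
        f[inside] = spec.level
    return FibrosisMap(values=f, dx=dx)


def sample_texture(fmap: FibrosisMap, seed: int) -> ObstacleTexture:
    """Draw the obstacle texture: node i is an uncoupled unexcitable obstacle
    iff a per-node uniform variate is below f_i / 100.

    The uniform field depends only on (shape, seed), so the same seed gives
    reproducible textures and pointwise-larger maps give supersets of
    obstacles.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(fmap.shape)
    mask = u < fmap.normalized_si()
    return ObstacleTexture(mask=mask, seed=int(seed), map_hash=fmap.hash())


def make_scar_grid(spec: ScarSpec, shape: Tuple[int, int], seed: int,
                   dx: float = DX_CM) -> TissueGrid:
    """Convenience: fibrosis map + texture + grid in one call."""
    fmap = make_fibrosis_map(spec, shape, dx)
    tex = sample_texture(fmap, seed)
    return TissueGrid(n_rows=shape[0], n_cols=shape[1], dx=dx,
                      obstacle_mask=tex.mask, fibrosis_map=fmap.values)


def make_controls(spec: ScarSpec, shape: Tuple[int, int],
                  dx: float = DX_CM) -> Tuple[TissueGrid, TissueGrid]:
    """Control geometries for the anchoring experiments.

    Returns ``(no_scar, necrotic_only)``: a fully homogeneous grid, and a
    grid whose scar disk is solid obstacle (fibrosis 100 % inside, 0 %
    outside — no partially fibrotic border, no remodeling gradient).
    """
    rows, cols = shape
    no_scar = TissueGrid(n_rows=rows, n_cols=cols, dx=dx)

    r = _radius_grid(shape, spec.center, dx)
    solid = r < spec.radius_cm
    f = np.where(solid, 100.0, 0.0)
    necrotic = TissueGrid(n_rows=rows, n_cols=cols, dx=dx,
                          obstacle_mask=solid, fibrosis_map=f)
    return no_scar, necrotic
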