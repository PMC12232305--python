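"""2D Perlin gradient noise with fractal octaves.

Classic lattice gradient noise (random unit gradients on integer grid
points, quintic-smoothstep interpolation of the dot products), summed
over octaves with doubling frequency (lacunarity 2) and halving
amplitude (persistence 0.5).  Used to generate smooth, spatially
correlated fields for channel-fraction maps and blob-like intensity
images.
"""

from __future__ import annotations

import numpy as np


def _fade(t: np.ndarray) -> np.ndarray:
    # quintic smoothstep 6t^5 - 15t^4 + 10t^3
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def _single_octave(shape: tuple, cells: int, rng: np.random.Generator) -> np.ndarray:
    """One octave of gradient noise with ``cells`` lattice cells along the
    longer image side."""
    rows, cols = shape
    n = max(rows, cols)
    # lattice of random unit gradients
    gy, gx = np.meshgrid(
        np.arange(cells + 1), np.arange(cells + 1), indexing="ij"
    )
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(cells + 1, cells + 1))
    grad = np.stack([np.cos(theta), np.sin(theta)], axis=-1)

    # sample coordinates in lattice units
    ys = np.linspace(0.0, cells, rows, endpoint=False)
    xs = np.linspace(0.0, cells, cols, endpoint=False)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    y0 = np.floor(yy).astype(int)
    x0 = np.floor(xx).astype(int)
    fy = yy - y0
    fx = xx - x0

    def dot(dy: int, dx: int) -> np.ndarray:
        g = grad[y0 + dy, x0 + dx]
        return g[..., 0] * (fx - dx) + g[..., 1] * (fy - dy)

    u = _fade(fx)
    v = _fade(fy)
    top = dot(0, 0) * (1 - u) + dot(0, 1) * u
    bot = dot(1, 0) * (1 - u) + dot(1, 1) * u
    return top * (1 - v) + bot * v


def perlin_field(
    shape: tuple,
    rng: np.random.Generator,
    octaves: int = 3,
    base_cells: int = 8,
    persistence: float = 0.5,
    lacunarity: float = 2.0,
) -> np.ndarray:
    """Fractal Perlin noise field on ``shape``, roughly in [-1, 1].

    ``base_cells`` sets the feature scale of the first octave: the image
    is divided into that many lattice cells along its longer side, so the
    default gives features of about 1/8 of the image width.
    """
    field = np.zeros(shape, dtype=float)
    amp = 1.0
    cells = base_cells
    for _ in range(octaves):
        field += amp * _single_octave(shape, int(cells), rng)
        amp *= persistence
        cells *= lacunarity
    return field
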