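"""Synthetic TCSPC-FLIM image simulation with per-pixel ground truth.

Each simulated image starts from smooth "structure channel" intensity
images (a procedural stand-in for single-cell fluorescence micrographs).
Every channel carries a base lifetime in [0.1, 10] ns plus pixel-level
variability; Perlin-noise fraction maps mix the channels per pixel; and
every non-background pixel receives a decay histogram

    y(t) = IRF (*) sum_i a_i exp(-t / tau_i) + Poisson noise,

scaled so the noiseless histogram sums to that pixel's photon target
(100-2500 photons for the high-count regime, 10-100 for the low-count
regime).  The ground truth is the per-pixel average lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .axes import TimeAxis, default_axis
from .irf import IRFCurve, delta_irf
from .perlin import perlin_field

LIFETIME_MIN_NS = 0.1
LIFETIME_MAX_NS = 10.0
PHOTON_REGIMES = {"high": (100, 2500), "low": (10, 100)}


@dataclass
class ChannelSpec:
    """One simulated structure channel: an intensity image, a base
    lifetime (ns), a variability half-range (ns) and the resulting
    per-pixel lifetime map."""

    intensity: np.ndarray
    base_lifetime: float
    variability: float
    lifetime_map: np.ndarray


@dataclass
class FLIMStack:
    """3D photon-count histogram, laid out (time, row, col)."""

    counts: np.ndarray
    axis: TimeAxis
    irf_id: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError(f"counts must be 3D (time, row, col), got {self.counts.ndim}D")
        if self.counts.shape[0] != self.axis.n_bins:
            raise ValueError(
                f"time dimension {self.counts.shape[0]} does not match axis "
                f"with {self.axis.n_bins} bins"
            )
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")

    @property
    def spatial_shape(self) -> tuple:
        return self.counts.shape[1:]

    def total_counts(self) -> np.ndarray:
        """Per-pixel photon totals (row, col)."""
        return self.counts.sum(axis=0)


@dataclass
class LifetimeMap:
    """Per-pixel average lifetime (ns); 0 on background."""

    tau: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.tau.shape != self.background_mask.shape:
            raise ValueError("tau and background_mask shapes differ")


@dataclass
class FractionMaps:
    """Per-channel fractional contributions a_i; sums to 1 per pixel."""

    fractions: np.ndarray  # (n_channels, rows, cols)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 3:
            raise ValueError("fractions must be (n_channels, rows, cols)")

    @property
    def n_channels(self) -> int:
        return self.fractions.shape[0]


# ---------------------------------------------------------------------------
# channel construction


def synth_intensity_channels(shape, n_channels: int, seed: int) -> list[np.ndarray]:
    """Smooth blob/filament-like intensity channels.

    Thresholded fractal Perlin fields produce connected, cell-like
    structures; the union of non-background pixels always covers at
    least 5% of the frame.
    """
    rows, cols = shape
    if rows < 8 or cols < 8:
        raise ValueError(f"spatial shape {shape} too small; need >= 8 per side")
    if not 1 <= n_channels <= 4:
        raise ValueError(f"n_channels must be in 1..4, got {n_channels}")
    rng = np.random.default_rng(seed)
    channels = []
    for _ in range(n_channels):
        f = perlin_field((rows, cols), rng)
        # keep the brightest ~20% of the field as structure
        thr = np.quantile(f, 0.8)
        img = np.clip(f - thr, 0.0, None)
        channels.append(img)
    union = np.zeros((rows, cols), dtype=bool)
    for img in channels:
        union |= img > 0
    if union.mean() < 0.05:
        raise RuntimeError("structure coverage below 5% of the frame")
    return channels


def assign_channel_lifetimes(
    channels: list[np.ndarray],
    seed: int,
    variability_override: float | None = None,
) -> list[ChannelSpec]:
    """Attach lifetimes to channels.

    Per channel: base ~ U[0.1, 10] ns, variability ~ U[0.2, 2] ns, and a
    per-pixel lifetime base + U[-variability, +variability] clipped back
    to [0.1, 10] ns.  ``variability_override`` fixes the half-range
    (0 gives a constant map equal to the base).
    """
    if not channels:
        raise ValueError("channel list must be non-empty")
    rng = np.random.default_rng(seed)
    specs = []
    for img in channels:
        base = float(rng.uniform(LIFETIME_MIN_NS, LIFETIME_MAX_NS))
        if variability_override is None:
            var = float(rng.uniform(0.2, 2.0))
        else:
            var = float(variability_override)
        jitter = rng.uniform(-var, var, size=img.shape) if var > 0 else 0.0
        tau = np.clip(base + jitter, LIFETIME_MIN_NS, LIFETIME_MAX_NS)
        tau = np.broadcast_to(tau, img.shape).copy()
        specs.append(ChannelSpec(intensity=img, base_lifetime=base, variability=var, lifetime_map=tau))
    return specs


def perlin_fraction_maps(shape, n_channels: int, seed: int) -> FractionMaps:
    """Smooth per-channel fraction fields normalised to sum to 1 per pixel."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    fields = []
    for _ in range(n_channels):
        f = perlin_field(shape, rng)
        fields.append(f - f.min() + 1e-6)  # strictly positive
    stack = np.stack(fields)
    return FractionMaps(fractions=stack / stack.sum(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# decay synthesis


def _causal_convolve(decays: np.ndarray, irf_values: np.ndarray) -> np.ndarray:
    """Causal linear convolution along the last axis, truncated to n_bins.

    A delta IRF (single unit bin at t=0) is the identity.
    """
    n = decays.shape[-1]
    out = fftconvolve(decays, irf_values[(None,) * (decays.ndim - 1)], axes=-1)[..., :n]
    return np.clip(out, 0.0, None)


def simulate_pixel_decay(
    fractions,
    lifetimes,
    irf: IRFCurve,
    photons: float,
    axis: TimeAxis | None = None,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Single-pixel decay histogram.

    Builds sum_i a_i exp(-t/tau_i), convolves with the IRF, scales the
    noiseless curve to sum to ``photons``, then (with ``noise``) draws
    each bin from a Poisson law with that bin's mean.
    """
    a = np.asarray(fractions, dtype=float)
    tau = np.asarray(lifetimes, dtype=float)
    if a.shape != tau.shape:
        raise ValueError(f"fractions {a.shape} and lifetimes {tau.shape} differ in length")
    if a.size == 0 or a.size > 4:
        raise ValueError("between 1 and 4 decay components are supported")
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    if photons < 0:
        raise ValueError(f"photon target must be >= 0, got {photons}")
    axis = axis or irf.axis
    t = axis.times
    model = (a[:, None] * np.exp(-t[None, :] / tau[:, None])).sum(axis=0)
    model = np.convolve(model, irf.values)[: axis.n_bins]
    total = model.sum()
    if total <= 0 or photons == 0:
        return np.zeros(axis.n_bins, dtype=int if noise else float)
    model = model * (photons / total)
    if not noise:
        return model
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(model).astype(np.int64)


def normalize_decay(counts: np.ndarray) -> np.ndarray:
    """Scale a decay to peak 1; all-zero input passes through unchanged."""
    counts = np.asarray(counts, dtype=float)
    peak = counts.max()
    return counts if peak == 0 else counts / peak


def ground_truth_lifetime(fractions, lifetimes, weighting: str = "amplitude") -> float:
    """Average lifetime of a mixture.

    ``amplitude`` (default): sum_i a_i tau_i.  ``intensity``: weights each
    component by its photon share a_i tau_i instead.
    """
    a = np.asarray(fractions, dtype=float)
    tau = np.asarray(lifetimes, dtype=float)
    if a.size == 0:
        raise ValueError("empty mixture")
    if weighting == "amplitude":
        return float(np.sum(a * tau))
    if weighting == "intensity":
        w = a * tau
        return float(np.sum(w * tau) / np.sum(w))
    raise ValueError(f"unknown weighting {weighting!r}")


def scale_to_photon_range(composite: np.ndarray, regime, mask: np.ndarray) -> np.ndarray:
    """Map non-background composite intensities affinely onto the regime's
    photon range, rounded to integers; background pixels get 0."""
    lo, hi = PHOTON_REGIMES[regime] if isinstance(regime, str) else regime
    composite = np.asarray(composite, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    targets = np.zeros(composite.shape, dtype=np.int64)
    vals = composite[mask]
    if vals.size == 0:
        return targets
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        targets[mask] = int(round((lo + hi) / 2))
    else:
        scaled = lo + (composite[mask] - vmin) / (vmax - vmin) * (hi - lo)
        targets[mask] = np.round(scaled).astype(np.int64)
    return targets


def _simulate_stack_from_maps(
    fraction_maps: np.ndarray,
    lifetime_maps: np.ndarray,
    targets: np.ndarray,
    irf: IRFCurve,
    axis: TimeAxis,
    rng: np.random.Generator,
    noise: bool = True,
) -> np.ndarray:
    """Vectorised decay synthesis for a whole frame.

    ``fraction_maps``/``lifetime_maps`` are (n_channels, rows, cols);
    ``targets`` the per-pixel pre-noise photon totals (0 = background).
    """
    n_ch, rows, cols = fraction_maps.shape
    t = axis.times
    flat_mask = targets.reshape(-1) > 0
    n_pix = int(flat_mask.sum())
    stack = np.zeros((axis.n_bins, rows * cols))
    if n_pix:
        a = fraction_maps.reshape(n_ch, -1)[:, flat_mask]
        tau = lifetime_maps.reshape(n_ch, -1)[:, flat_mask]
        model = np.zeros((n_pix, axis.n_bins))
        for c in range(n_ch):
            model += a[c][:, None] * np.exp(-t[None, :] / tau[c][:, None])
        model = _causal_convolve(model, irf.values)
        sums = model.sum(axis=1)
        sums[sums == 0] = 1.0
        model *= (targets.reshape(-1)[flat_mask] / sums)[:, None]
        stack[:, flat_mask] = model.T
    stack = stack.reshape(axis.n_bins, rows, cols)
    if noise:
        stack = rng.poisson(stack).astype(np.int64)
    return stack


def simulate_flim_image(
    shape=(64, 64),
    n_channels: int = 4,
    irf: IRFCurve | None = None,
    regime: str = "high",
    seed: int = 0,
    noise: bool = True,
    weighting: str = "amplitude",
):
    """Simulate one annotated FLIM image.

    Returns ``(FLIMStack, LifetimeMap)``; the map holds the per-pixel
    average lifetime on non-background pixels and 0 on background.
    """
    irf = irf or delta_irf()
    axis = irf.axis
    rng = np.random.default_rng(seed)
    sub = rng.integers(2**31, size=4)
    channels = synth_intensity_channels(shape, n_channels, seed=int(sub[0]))
    specs = assign_channel_lifetimes(channels, seed=int(sub[1]))
    fracs = perlin_fraction_maps(shape, n_channels, seed=int(sub[2]))

    composite = np.sum([s.intensity for s in specs], axis=0)
    non_bg = composite > 0
    targets = scale_to_photon_range(composite, regime, non_bg)

    lifetime_maps = np.stack([s.lifetime_map for s in specs])
    tau_map = np.sum(fracs.fractions * lifetime_maps, axis=0)
    if weighting == "intensity":
        w = fracs.fractions * lifetime_maps
        tau_map = np.sum(w * lifetime_maps, axis=0) / np.sum(w, axis=0)
    tau_map = np.where(non_bg, tau_map, 0.0)

    noise_rng = np.random.default_rng(int(sub[3]))
    counts = _simulate_stack_from_maps(
        fracs.fractions, lifetime_maps, targets, irf, axis, noise_rng, noise=noise
    )
    stack = FLIMStack(
        counts=counts,
        axis=axis,
        irf_id=irf.meta.get("kind", "simulated"),
        meta={"regime": regime, "seed": seed, "photon_targets": targets},
    )
    return stack, LifetimeMap(tau=tau_map, background_mask=~non_bg)


# ---------------------------------------------------------------------------
# benchmark fixtures


def _flower_mask(size: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Boolean petal mask and 2x2 center mask for a rose-curve flower."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)
    petal_r = (size * 0.45) * (0.55 + 0.45 * np.abs(np.cos(2 * theta)))
    flower = r <= petal_r
    center = np.zeros((size, size), dtype=bool)
    half = size // 2
    center[half - 1 : half + 1, half - 1 : half + 1] = True
    petals = flower & ~center
    return petals, center


def flower_fixture(
    n_images: int,
    seed: int,
    size: int = 16,
    irf: IRFCurve | None = None,
    axis: TimeAxis | None = None,
) -> list[tuple[FLIMStack, LifetimeMap]]:
    """Flower-pattern test images: 4 central pixels at 1 ns surrounded by
    petal pixels drawn from U[4, 6] ns, 20 photons per pixel (pre-noise)."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    axis = axis or default_axis()
    irf = irf or delta_irf(axis)
    petals, center = _flower_mask(size)
    non_bg = petals | center
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        tau_map = np.zeros((size, size))
        tau_map[center] = 1.0
        tau_map[petals] = rng.uniform(4.0, 6.0, size=int(petals.sum()))
        targets = np.where(non_bg, 20, 0).astype(np.int64)
        counts = _simulate_stack_from_maps(
            tau_map[None], np.where(tau_map > 0, tau_map, 1.0)[None],
            targets, irf, axis, rng,
        )
        # fractions are trivially 1 for the single local component
        counts_stack = FLIMStack(
            counts=counts, axis=axis, irf_id=irf.meta.get("kind", "simulated"),
            meta={"fixture": "flower", "photon_target": 20},
        )
        out.append((counts_stack, LifetimeMap(tau=tau_map, background_mask=~non_bg)))
    return out


def uniform_and_single_pixel_fixture(
    n_images: int,
    seed: int,
    size: int = 28,
    pixel=(10, 10),
    photons: int = 100,
    irf: IRFCurve | None = None,
    axis: TimeAxis | None = None,
) -> list[tuple[FLIMStack, FLIMStack, float]]:
    """Spatial-context probe pairs.

    Each pair is a full image where every pixel shares one mono-exponential
    lifetime drawn from U[0.4, 6] ns (100-photon target, Poisson noise) and
    a masked copy that is zero everywhere except the pixel at ``pixel``,
    which is bitwise identical to the full image's pixel.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    axis = axis or default_axis()
    irf = irf or delta_irf(axis)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        tau = float(rng.uniform(0.4, 6.0))
        targets = np.full((size, size), photons, dtype=np.int64)
        counts = _simulate_stack_from_maps(
            np.ones((1, size, size)), np.full((1, size, size), tau),
            targets, irf, axis, rng,
        )
        full = FLIMStack(counts=counts, axis=axis, meta={"tau": tau})
        masked_counts = np.zeros_like(counts)
        masked_counts[:, pixel[0], pixel[1]] = counts[:, pixel[0], pixel[1]]
        masked = FLIMStack(counts=masked_counts, axis=axis, meta={"tau": tau})
        out.append((full, masked, tau))
    return out


def two_region_fixture(
    n_images: int,
    seed: int,
    size: int = 28,
    taus=(1.0, 4.0),
    photons: int = 200,
    axis: TimeAxis | None = None,
    irf: IRFCurve | None = None,
) -> list[tuple[FLIMStack, LifetimeMap]]:
    """Easy two-region training images: each frame split into two regions
    with fixed lifetimes, every pixel at the same photon target.

    The split orientation (vertical/horizontal/diagonal) and boundary
    position vary per image so the network cannot memorise geometry.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    axis = axis or TimeAxis(bin_width=0.3908, n_bins=64)
    irf = irf or delta_irf(axis)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    out = []
    for _ in range(n_images):
        kind = rng.integers(3)
        cut = rng.uniform(0.3, 0.7) * size
        if kind == 0:
            region = xx < cut
        elif kind == 1:
            region = yy < cut
        else:
            region = (xx + yy) < 2 * cut
        tau_map = np.where(region, taus[0], taus[1]).astype(float)
        targets = np.full((size, size), photons, dtype=np.int64)
        counts = _simulate_stack_from_maps(
            np.ones((1, size, size)), tau_map[None], targets, irf, axis, rng
        )
        out.append((
            FLIMStack(counts=counts, axis=axis, meta={"fixture": "two_region"}),
            LifetimeMap(tau=tau_map, background_mask=np.zeros((size, size), dtype=bool)),
        ))
    return out


def subsample_photons(stack: FLIMStack, per_pixel_targets: np.ndarray, seed: int) -> FLIMStack:
    """Thin each pixel's histogram to an exact photon target by drawing
    without replacement (multivariate hypergeometric)."""
    targets = np.asarray(per_pixel_targets)
    totals = stack.total_counts()
    if targets.shape != totals.shape:
        raise ValueError("target map shape does not match stack spatial shape")
    over = targets > totals
    if np.any(over):
        r, c = np.argwhere(over)[0]
        raise ValueError(
            f"target {targets[r, c]} exceeds available {totals[r, c]} photons "
            f"at pixel ({r}, {c})"
        )
    rng = np.random.default_rng(seed)
    counts = np.asarray(stack.counts, dtype=np.int64)
    out = counts.copy()
    rows, cols = totals.shape
    for r in range(rows):
        for c in range(cols):
            if targets[r, c] < totals[r, c]:
                out[:, r, c] = rng.multivariate_hypergeometric(
                    counts[:, r, c], int(targets[r, c])
                )
    return FLIMStack(
        counts=out, axis=stack.axis, irf_id=stack.irf_id,
        meta={**stack.meta, "subsampled": True},
    )
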