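"""Masked MSE scoring and desk-scale benchmark suites.

Accuracy is the mean squared error between predicted and ground-truth
lifetime maps, computed only over non-background ground-truth pixels so
methods that smear lifetimes into the background are not unfairly
penalised (or rewarded).  The benchmark suites sweep photon counts,
IRF widths, and spatial context with ground truths held fixed across
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axes import TimeAxis, default_axis
from .irf import IRFCurve, compose_irf, secondary_peak, shift_peak, sigma_from_fwhm, skew_normal_primary
from .simulate import (
    LifetimeMap,
    FLIMStack,
    _simulate_stack_from_maps,
    assign_channel_lifetimes,
    perlin_fraction_maps,
    scale_to_photon_range,
    synth_intensity_channels,
    uniform_and_single_pixel_fixture,
)


def mse_map(pred: LifetimeMap, truth: LifetimeMap, mask: np.ndarray) -> float:
    """Mean squared error (ns^2) over pixels where ``mask`` is True."""
    mask = np.asarray(mask, dtype=bool)
    if pred.tau.shape != truth.tau.shape or pred.tau.shape != mask.shape:
        raise ValueError("prediction, truth and mask shapes must match")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no pixels to score")
    diff = pred.tau[mask] - truth.tau[mask]
    return float(np.mean(diff * diff))


@dataclass
class BenchmarkResult:
    """Tidy per-image scores with condition labels."""

    table: pd.DataFrame  # columns: image_id, condition, method, mse

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("condition")["mse"]
        out = g.agg(["mean", "std", "median"])
        out["iqr"] = g.quantile(0.75) - g.quantile(0.25)
        out["n"] = g.size()
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _scene(shape, n_channels: int, seed: int):
    """One fixed simulation scene: channel structure, lifetimes, fractions
    and the resulting ground-truth map (photon regime applied later)."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(2**31, size=3)
    channels = synth_intensity_channels(shape, n_channels, seed=int(sub[0]))
    specs = assign_channel_lifetimes(channels, seed=int(sub[1]))
    fracs = perlin_fraction_maps(shape, n_channels, seed=int(sub[2]))
    composite = np.sum([s.intensity for s in specs], axis=0)
    non_bg = composite > 0
    lifetime_maps = np.stack([s.lifetime_map for s in specs])
    tau_map = np.where(non_bg, np.sum(fracs.fractions * lifetime_maps, axis=0), 0.0)
    truth = LifetimeMap(tau=tau_map, background_mask=~non_bg)
    return fracs.fractions, lifetime_maps, composite, non_bg, truth


def _zero_skew_irf(fwhm_ps: float, axis: TimeAxis, peak_bin: int = 20,
                   skew: float = 2.0) -> IRFCurve:
    """A single simulated IRF of the given width, for benchmark sweeps."""
    mu = axis.span / 2.0
    sigma = sigma_from_fwhm(fwhm_ps)
    primary = skew_normal_primary(axis, mu, sigma, skew)
    sec = secondary_peak(axis, mu + 1.0, sigma)
    curve = compose_irf(primary, sec, 0.0, axis, meta={"target_fwhm": fwhm_ps, "skew": skew})
    return shift_peak(curve, peak_bin)


def photon_series_benchmark(
    method,
    photon_levels=(100, 80, 50, 20, 10),
    n_images: int = 5,
    seed: int = 0,
    shape=(32, 32),
    n_channels: int = 3,
    irf: IRFCurve | None = None,
    method_name: str = "method",
) -> BenchmarkResult:
    """Sweep uniform per-pixel photon targets with fixed ground truths.

    ``method`` is a ``FLIMStack -> LifetimeMap`` callable.  For each image
    the scene (structure, lifetimes, fractions) is built once from the
    seed, then re-simulated at every photon level with fresh Poisson
    noise, so ground-truth maps are identical across levels.
    """
    axis = irf.axis if irf is not None else default_axis()
    from .irf import delta_irf

    irf = irf or delta_irf(axis)
    rows = []
    for i in range(n_images):
        fracs, lifetimes, composite, non_bg, truth = _scene(shape, n_channels, seed + i)
        for level in photon_levels:
            targets = np.where(non_bg, int(level), 0).astype(np.int64)
            noise_rng = np.random.default_rng(hash((seed, i, level)) % 2**31)
            counts = _simulate_stack_from_maps(fracs, lifetimes, targets, irf, axis, noise_rng)
            stack = FLIMStack(counts=counts, axis=axis, meta={"photons": level})
            pred = method(stack)
            rows.append({
                "image_id": i, "condition": level, "method": method_name,
                "mse": mse_map(pred, truth, ~truth.background_mask),
            })
    return BenchmarkResult(table=pd.DataFrame(rows))


def irf_width_benchmark(
    method,
    fwhms=(220.0, 400.0, 800.0),
    n_images: int = 5,
    seed: int = 0,
    shape=(32, 32),
    n_channels: int = 3,
    regime: str = "high",
    method_name: str = "method",
) -> BenchmarkResult:
    """Sweep IRF widths (high-photon-count regime, fixed ground truths)."""
    axis = default_axis()
    rows = []
    for i in range(n_images):
        fracs, lifetimes, composite, non_bg, truth = _scene(shape, n_channels, seed + i)
        targets = scale_to_photon_range(composite, regime, non_bg)
        for fwhm in fwhms:
            irf = _zero_skew_irf(fwhm, axis)
            noise_rng = np.random.default_rng(hash((seed, i, fwhm)) % 2**31)
            counts = _simulate_stack_from_maps(fracs, lifetimes, targets, irf, axis, noise_rng)
            stack = FLIMStack(counts=counts, axis=axis, meta={"fwhm": fwhm})
            pred = method(stack)
            rows.append({
                "image_id": i, "condition": fwhm, "method": method_name,
                "mse": mse_map(pred, truth, ~truth.background_mask),
            })
    return BenchmarkResult(table=pd.DataFrame(rows))


def context_benchmark(
    method,
    n_images: int = 10,
    seed: int = 0,
    pixel=(10, 10),
    method_name: str = "method",
    axis: TimeAxis | None = None,
    size: int = 28,
) -> BenchmarkResult:
    """Spatial-context probe: squared error at one pixel when the method
    sees the full image versus a copy where every other pixel is zeroed."""
    pairs = uniform_and_single_pixel_fixture(n_images, seed, size=size, pixel=pixel, axis=axis)
    rows = []
    for i, (full, masked, tau) in enumerate(pairs):
        for condition, stack in (("full", full), ("masked", masked)):
            pred = method(stack)
            err = float((pred.tau[pixel] - tau) ** 2)
            rows.append({"image_id": i, "condition": condition,
                         "method": method_name, "mse": err})
    return BenchmarkResult(table=pd.DataFrame(rows))
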