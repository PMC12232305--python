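"""Parametric instrument response functions (IRFs) for TCSPC simulation.

The measured decay of a TCSPC system is the true fluorescence decay
convolved with the instrument response — the temporal spread the
detection chain imprints on an instantaneous light pulse.  Real IRFs are
slightly asymmetric (detector transit-time skew) and frequently show a
delayed secondary bump from after-pulsing.  This module builds such
curves from a skew-normal primary peak plus an optional Gaussian
secondary peak:

    IRF(t) = SN(t; mu, sigma, lambda) + a * N(t; mu', sigma'),

normalised so the maximum equals 1, and provides peak shifting so a
library of IRFs spans a range of peak positions (laser-jitter surrogate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .axes import TimeAxis, default_axis

PS_PER_NS = 1000.0

#: FWHM = 2 * sqrt(2 ln 2) * sigma for a Gaussian.
GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class IRFCurve:
    """A normalised IRF sampled on a :class:`TimeAxis`.

    ``values`` is nonnegative with maximum 1; ``meta`` records the
    generation parameters (target FWHM in ps, skew, peak locations).
    """

    values: np.ndarray
    axis: TimeAxis
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.axis.n_bins:
            raise ValueError(
                f"IRF length {self.values.size} does not match axis with "
                f"{self.axis.n_bins} bins"
            )
        if np.any(self.values < 0):
            raise ValueError("IRF values must be nonnegative")

    @property
    def peak_bin(self) -> int:
        """Index of the maximum value."""
        return int(np.argmax(self.values))


@dataclass
class IRFLibraryConfig:
    """Sampling ranges for a randomised IRF library.

    Defaults reproduce the simulation conditions used throughout this
    package: three FWHM classes (220/400/800 ps), positive skew in
    [1, 5], an after-pulsing peak present half the time with amplitude
    up to 0.2 and a 0.5–2 ns delay, and peak positions shifted to bins
    12–58 (inclusive, 0-based).
    """

    fwhm_choices: tuple = (220.0, 400.0, 800.0)
    skew_range: tuple = (1.0, 5.0)
    secondary_amp_range: tuple = (0.0, 0.2)
    secondary_prob: float = 0.5
    secondary_offset_range: tuple = (0.5, 2.0)
    peak_bin_range: tuple = (12, 58)
    n_irfs: int = 100
    seed: int = 0
    axis: TimeAxis = field(default_factory=default_axis)

    def __post_init__(self) -> None:
        if len(self.fwhm_choices) == 0:
            raise ValueError("fwhm_choices must not be empty")
        if any(f <= 0 for f in self.fwhm_choices):
            raise ValueError("all FWHM choices must be positive")
        lo, hi = self.peak_bin_range
        if not (0 <= lo <= hi < self.axis.n_bins):
            raise ValueError(
                f"peak_bin_range {self.peak_bin_range} outside "
                f"[0, {self.axis.n_bins - 1}]"
            )
        if self.n_irfs < 0:
            raise ValueError("n_irfs must be >= 0")


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian standard deviation (ps) for a target FWHM (ps).

    sigma = FWHM / (2 * sqrt(2 ln 2)).
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm}")
    return fwhm / GAUSSIAN_FWHM_FACTOR


def skew_normal_primary(
    axis: TimeAxis, mu: float, sigma: float, skew: float
) -> np.ndarray:
    """Skew-normal density 2*phi(z)*Phi(lambda*z)/sigma on the axis.

    Parameters
    ----------
    mu : float
        Peak-location parameter in ns.
    sigma : float
        Scale parameter in ps.
    skew : float
        Shape parameter lambda; 0 gives a symmetric Gaussian.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    sigma_ns = sigma / PS_PER_NS
    z = (axis.times - mu) / sigma_ns
    return 2.0 / sigma_ns * stats.norm.pdf(z) * stats.norm.cdf(skew * z)


def secondary_peak(axis: TimeAxis, mu2: float, sigma2: float) -> np.ndarray:
    """Gaussian after-pulsing peak: N(mu2, sigma2) density on the axis.

    ``mu2`` in ns, ``sigma2`` in ps.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    return stats.norm.pdf(axis.times, loc=mu2, scale=sigma2 / PS_PER_NS)


def compose_irf(
    primary: np.ndarray,
    secondary: np.ndarray,
    amp: float,
    axis: TimeAxis,
    meta: dict | None = None,
) -> IRFCurve:
    """Combine primary + amp*secondary and normalise the maximum to 1."""
    primary = np.asarray(primary, dtype=float)
    secondary = np.asarray(secondary, dtype=float)
    if primary.shape != secondary.shape or primary.size != axis.n_bins:
        raise ValueError(
            f"component shapes {primary.shape}/{secondary.shape} do not match "
            f"axis with {axis.n_bins} bins"
        )
    if amp < 0:
        raise ValueError(f"secondary amplitude must be >= 0, got {amp}")
    total = primary + amp * secondary
    peak = total.max()
    if peak <= 0:
        raise ValueError("degenerate IRF: composed curve is identically zero")
    return IRFCurve(values=total / peak, axis=axis, meta=dict(meta or {}))


def measure_fwhm(curve: IRFCurve) -> float:
    """Full width at half maximum in ps, by linear interpolation.

    Finds the outermost crossings of ``values == max/2`` on either side
    of the peak and interpolates between the adjacent bins.
    """
    v = curve.values
    peak = int(np.argmax(v))
    half = v[peak] / 2.0
    t = curve.axis.times

    def _crossing(lo_side: bool) -> float:
        idx = range(peak, -1, -1) if lo_side else range(peak, len(v))
        prev = peak
        for i in idx:
            if v[i] < half:
                # interpolate between bin i (below) and prev (above)
                frac = (half - v[i]) / (v[prev] - v[i])
                return t[i] + frac * (t[prev] - t[i])
            prev = i
        raise ValueError(
            "curve never falls below half maximum on the "
            + ("left" if lo_side else "right")
            + " side; FWHM is undefined"
        )

    return (_crossing(False) - _crossing(True)) * PS_PER_NS


def shift_peak(curve: IRFCurve, target_bin: int) -> IRFCurve:
    """Integer-bin shift placing the peak at ``target_bin``; vacated bins
    are zero-filled (mass shifted past the window edge is dropped)."""
    n = curve.axis.n_bins
    if not 0 <= target_bin < n:
        raise ValueError(f"target_bin {target_bin} outside [0, {n - 1}]")
    delta = int(target_bin) - curve.peak_bin
    shifted = np.zeros_like(curve.values)
    if delta >= 0:
        shifted[delta:] = curve.values[: n - delta]
    else:
        shifted[: n + delta] = curve.values[-delta:]
    peak = shifted.max()
    if peak <= 0:
        raise ValueError("shift moved the entire IRF out of the window")
    meta = dict(curve.meta)
    meta["peak_bin"] = int(np.argmax(shifted))
    return IRFCurve(values=shifted / peak, axis=curve.axis, meta=meta)


def delta_irf(axis: TimeAxis | None = None, bin: int = 0) -> IRFCurve:
    """Idealised IRF: a single unit bin (identity under convolution)."""
    axis = axis or default_axis()
    values = np.zeros(axis.n_bins)
    values[bin] = 1.0
    return IRFCurve(values=values, axis=axis, meta={"kind": "delta"})


def sample_irf_library(config: IRFLibraryConfig) -> list[IRFCurve]:
    """Draw ``config.n_irfs`` randomised IRFs.

    Each curve draws a FWHM class, skew, optional secondary peak and a
    target peak bin from the configured ranges using a generator seeded
    with ``config.seed`` — the library is a pure function of the config.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.axis
    # generation peak placed mid-window, away from edges; the subsequent
    # integer shift sets the final peak position
    mu = axis.span / 2.0
    out: list[IRFCurve] = []
    for _ in range(config.n_irfs):
        fwhm = float(rng.choice(np.asarray(config.fwhm_choices, dtype=float)))
        sigma = sigma_from_fwhm(fwhm)
        lam = float(rng.uniform(*config.skew_range))
        primary = skew_normal_primary(axis, mu, sigma, lam)
        if rng.random() < config.secondary_prob:
            amp = float(rng.uniform(*config.secondary_amp_range))
            offset = float(rng.uniform(*config.secondary_offset_range))
            sigma2 = float(rng.uniform(0.5 * sigma, 1.5 * sigma))
        else:
            amp, offset, sigma2 = 0.0, 1.0, sigma
        sec = secondary_peak(axis, mu + offset, sigma2)
        meta = {
            "target_fwhm": fwhm,
            "skew": lam,
            "peak_loc": mu,
            "sigma": sigma,
            "secondary_amp": amp,
            "secondary_loc": mu + offset,
            "secondary_sigma": sigma2,
        }
        curve = compose_irf(primary, sec, amp, axis, meta=meta)
        target = int(rng.integers(config.peak_bin_range[0], config.peak_bin_range[1] + 1))
        out.append(shift_peak(curve, target))
    return out


def save_irf_library(path, curves: list[IRFCurve]) -> None:
    """Write a library to HDF5: dataset ``values`` (n_irfs, n_bins) plus
    per-curve metadata attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        if curves:
            axis = curves[0].axis
            f.create_dataset("values", data=np.stack([c.values for c in curves]))
            f.attrs["bin_width_ns"] = axis.bin_width
            f.attrs["n_bins"] = axis.n_bins
            for i, c in enumerate(curves):
                grp = f.create_group(f"meta/{i}")
                for k, v in c.meta.items():
                    grp.attrs[k] = v
        else:
            f.attrs["n_bins"] = 0


def load_irf_library(path) -> list[IRFCurve]:
    """Read a library written by :func:`save_irf_library`."""
    import h5py

    with h5py.File(path, "r") as f:
        if "values" not in f:
            return []
        values = f["values"][()]
        axis = TimeAxis(bin_width=float(f.attrs["bin_width_ns"]), n_bins=int(f.attrs["n_bins"]))
        curves = []
        for i in range(values.shape[0]):
            meta = {}
            key = f"meta/{i}"
            if key in f:
                meta = {k: v for k, v in f[key].attrs.items()}
            curves.append(IRFCurve(values=values[i], axis=axis, meta=meta))
    return curves
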