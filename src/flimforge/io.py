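"""File IO, time-axis resampling, spatial padding/cropping and masking.

HDF5 is the canonical interchange format (dataset ``counts`` with
``bin_width_ns``/``n_bins``/``irf_id`` attributes); multi-page TIFF (one
page per time bin) is supported for interoperability.  TIFF carries no
temporal metadata, so the bin width must be declared explicitly on
import — it is never silently defaulted.  Vendor binaries (.sdt, .ptu)
are deliberately unsupported; convert to HDF5/TIFF upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .axes import TimeAxis
from .simulate import FLIMStack, LifetimeMap

RECOMMENDED_BIN_RANGE = (50, 1000)


@dataclass
class StackFile:
    """A FLIM stack on disk plus the metadata needed to interpret it."""

    path: str
    format: str = "auto"  # hdf5 | tiff | auto (from suffix)
    bin_width: float | None = None
    n_bins: int | None = None


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".sdt", ".ptu"):
        raise ValueError(
            f"vendor binary format {suffix} is not supported; export to .h5 or "
            ".tif (e.g. via the vendor software or fifo2tiff converters) first"
        )
    raise ValueError(f"unrecognized stack format for {path}")


def write_stack(path, stack: FLIMStack) -> None:
    """Write a stack as HDF5 (with metadata) or multi-page TIFF."""
    path = Path(path)
    fmt = _resolve_format(path, "auto")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=np.asarray(stack.counts))
            f.attrs["bin_width_ns"] = stack.axis.bin_width
            f.attrs["n_bins"] = stack.axis.n_bins
            f.attrs["irf_id"] = stack.irf_id
    else:
        tifffile.imwrite(path, np.asarray(stack.counts).astype(np.int32))


def read_stack(file, bin_width: float | None = None) -> FLIMStack:
    """Read a FLIM stack from disk.

    ``bin_width`` (ns) is required whenever the file itself carries no
    temporal metadata (always for TIFF).
    """
    if not isinstance(file, StackFile):
        file = StackFile(path=str(file), bin_width=bin_width)
    elif bin_width is not None:
        file.bin_width = bin_width
    path = Path(file.path)
    fmt = _resolve_format(path, file.format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            counts = f["counts"][()]
            bw = file.bin_width if file.bin_width is not None else f.attrs.get("bin_width_ns")
            irf_id = str(f.attrs.get("irf_id", "unknown"))
    else:
        counts = tifffile.imread(path)
        bw = file.bin_width
        irf_id = "unknown"
    if bw is None:
        raise ValueError(
            f"{path} carries no bin width; pass bin_width= (in ns) explicitly "
            "when importing"
        )
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValueError(f"{path} does not contain a 3D (time, row, col) stack")
    if np.any(counts < 0):
        raise ValueError(f"{path} contains negative photon counts")
    return FLIMStack(counts=counts.astype(np.int64), axis=TimeAxis(float(bw), counts.shape[0]),
                     irf_id=irf_id)


def write_lifetime_map(path, lt: LifetimeMap) -> None:
    """Lifetime map as 32-bit TIFF; mask in a sibling ``.mask.tif`` file."""
    path = Path(path)
    tifffile.imwrite(path, lt.tau.astype(np.float32))
    tifffile.imwrite(path.with_suffix(".mask.tif"), lt.background_mask.astype(np.uint8))


def read_lifetime_map(path) -> LifetimeMap:
    path = Path(path)
    tau = tifffile.imread(path).astype(float)
    mask_path = path.with_suffix(".mask.tif")
    if mask_path.exists():
        mask = tifffile.imread(mask_path).astype(bool)
    else:
        mask = tau == 0
    return LifetimeMap(tau=tau, background_mask=mask)


# ---------------------------------------------------------------------------
# temporal resampling


def resample_time_axis(stack: FLIMStack, target_bins: int = 256,
                       warn: bool = True) -> FLIMStack:
    """Photon-conserving temporal rebinning to ``target_bins``.

    Integer-ratio downsampling sums adjacent bins exactly.  Non-integer
    ratios distribute counts by fractional bin overlap, then round with a
    per-pixel largest-remainder correction so each pixel's total photon
    count is conserved exactly.  The bin width is rescaled so the record
    length is unchanged.
    """
    if target_bins < 1:
        raise ValueError("target_bins must be >= 1")
    n0 = stack.axis.n_bins
    if warn and not RECOMMENDED_BIN_RANGE[0] <= n0 <= RECOMMENDED_BIN_RANGE[1]:
        import warnings

        warnings.warn(
            f"original bin count {n0} outside the recommended range "
            f"{RECOMMENDED_BIN_RANGE}; downstream prediction accuracy may be "
            "compromised", stacklevel=2,
        )
    if target_bins == n0:
        return stack
    counts = np.asarray(stack.counts, dtype=np.int64)
    t, h, w = counts.shape
    new_width = stack.axis.span / target_bins
    if n0 % target_bins == 0:
        r = n0 // target_bins
        out = counts.reshape(target_bins, r, h, w).sum(axis=1)
    else:
        # fractional overlap matrix (target_bins x n0), rows sum to ratio
        w0 = stack.axis.bin_width
        edges_in = np.arange(n0 + 1) * w0
        edges_out = np.arange(target_bins + 1) * new_width
        lo = np.maximum(edges_in[None, :-1], edges_out[:-1, None])
        hi = np.minimum(edges_in[None, 1:], edges_out[1:, None])
        overlap = np.clip(hi - lo, 0.0, None) / w0
        flat = counts.reshape(t, -1)
        frac = overlap @ flat  # (target_bins, pixels) expected counts
        base = np.floor(frac).astype(np.int64)
        deficit = flat.sum(axis=0) - base.sum(axis=0)
        rem = frac - base
        out = base
        # largest-remainder rounding per pixel conserves totals exactly
        order = np.argsort(-rem, axis=0, kind="stable")
        for p in range(flat.shape[1]):
            d = int(deficit[p])
            if d > 0:
                out[order[:d, p], p] += 1
        out = out.reshape(target_bins, h, w)
    return FLIMStack(counts=out, axis=TimeAxis(new_width, target_bins),
                     irf_id=stack.irf_id, meta={**stack.meta, "resampled_from": n0})


# ---------------------------------------------------------------------------
# spatial geometry


def pad_crop_square(stack: FLIMStack, mode: str = "pad"):
    """Make the spatial footprint square by zero-padding the short axis
    (``pad``) or center-cropping the long axis (``crop``).

    Returns ``(stack, geometry)`` where geometry maps results back to the
    original footprint (see :func:`unmap_lifetime_map`).
    """
    h, w = stack.spatial_shape
    if h == 0 or w == 0:
        raise ValueError("cannot square a stack with an empty spatial dimension")
    geometry = {"mode": mode, "original_shape": (h, w), "row_off": 0, "col_off": 0}
    if h == w:
        return stack, geometry
    counts = np.asarray(stack.counts)
    if mode == "pad":
        side = max(h, w)
        pr, pc = side - h, side - w
        top, left = pr // 2, pc // 2
        out = np.zeros((counts.shape[0], side, side), dtype=counts.dtype)
        out[:, top : top + h, left : left + w] = counts
        geometry.update(row_off=top, col_off=left)
    elif mode == "crop":
        side = min(h, w)
        top, left = (h - side) // 2, (w - side) // 2
        out = counts[:, top : top + side, left : left + side]
        geometry.update(row_off=-top, col_off=-left)
    else:
        raise ValueError(f"mode must be 'pad' or 'crop', got {mode!r}")
    return (FLIMStack(counts=out, axis=stack.axis, irf_id=stack.irf_id, meta=stack.meta),
            geometry)


def unmap_lifetime_map(lt: LifetimeMap, geometry: dict) -> LifetimeMap:
    """Map a lifetime map computed on a squared stack back onto the
    original footprint (inverse of :func:`pad_crop_square`)."""
    h, w = geometry["original_shape"]
    if geometry["mode"] == "pad":
        top, left = geometry["row_off"], geometry["col_off"]
        return LifetimeMap(
            tau=lt.tau[top : top + h, left : left + w],
            background_mask=lt.background_mask[top : top + h, left : left + w],
        )
    top, left = -geometry["row_off"], -geometry["col_off"]
    tau = np.zeros((h, w))
    mask = np.ones((h, w), dtype=bool)
    side = lt.tau.shape[0]
    tau[top : top + side, left : left + side] = lt.tau
    mask[top : top + side, left : left + side] = lt.background_mask
    return LifetimeMap(tau=tau, background_mask=mask)


def intensity_mask(stack: FLIMStack, min_photons: int) -> np.ndarray:
    """Boolean mask: True where the per-pixel photon total is at least
    ``min_photons`` (inclusive threshold)."""
    if min_photons < 0:
        raise ValueError("min_photons must be >= 0")
    return stack.total_counts() >= min_photons
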