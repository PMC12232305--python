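"""Temporal grids shared by decays and instrument response functions.

A TCSPC histogram discretises photon arrival times onto a uniform grid.
The default grid used throughout this package is 256 bins of 0.0977 ns,
i.e. a 25 ns record matching a 40 MHz excitation laser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default TCSPC bin width in nanoseconds (40 MHz repetition rate, 256 bins).
DEFAULT_BIN_WIDTH_NS = 0.0977
#: Default number of time bins.
DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class TimeAxis:
    """Uniform time grid: bin ``k`` starts at ``k * bin_width`` nanoseconds.

    Parameters
    ----------
    bin_width : float
        Temporal bin width in ns; must be positive.
    n_bins : int
        Number of bins; at least 2.
    """

    bin_width: float = DEFAULT_BIN_WIDTH_NS
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        if int(self.n_bins) < 2 or self.n_bins != int(self.n_bins):
            raise ValueError(f"n_bins must be an integer >= 2, got {self.n_bins}")
        object.__setattr__(self, "n_bins", int(self.n_bins))

    @property
    def times(self) -> np.ndarray:
        """Bin start times ``k * bin_width`` in ns (0-based)."""
        return np.arange(self.n_bins) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        """Bin center times ``(k + 1/2) * bin_width`` in ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def span(self) -> float:
        """Total temporal record length in ns."""
        return self.bin_width * self.n_bins

    def __len__(self) -> int:
        return self.n_bins


def default_axis() -> TimeAxis:
    """The canonical simulation axis: 256 bins of 0.0977 ns."""
    return TimeAxis()
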