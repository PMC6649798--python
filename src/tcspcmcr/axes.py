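"""Core containers shared by every stage of the pipeline.

A TCSPC experiment produces histograms of photon arrival times: the
instrument response function (IRF, the scatter profile of the setup) and
one decay trace per (sequence, pH, emission wavelength) condition, all on
a common time axis.  The sum-of-exponentials decay law lives in
:class:`ExponentialModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TimeAxis",
    "InstrumentResponse",
    "DecayTrace",
    "ExponentialModel",
    "DegenerateIRFError",
]

#: FWHM of a Gaussian divided by its standard deviation.
FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


class DegenerateIRFError(ValueError):
    """Raised when a requested IRF does not fit on the time axis."""


@dataclass(frozen=True)
class TimeAxis:
    """Uniform histogram time axis.

    Parameters
    ----------
    n_bins : int
        Number of histogram channels.
    bin_width : float
        Channel width in ns.  The default (0.025 ns = 25 ps) is the bin
        time of the TimeHarp-class TCSPC boards this package emulates.
    origin : float
        Time of the first bin edge, ns.
    """

    n_bins: int
    bin_width: float = 0.025
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if not (self.bin_width > 0 and np.isfinite(self.bin_width)):
            raise ValueError(f"bin_width must be positive and finite, got {self.bin_width}")
        if not np.isfinite(self.origin):
            raise ValueError("origin must be finite")

    @property
    def centers(self) -> np.ndarray:
        """Bin-centre times in ns (strictly increasing)."""
        return self.origin + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def span(self) -> float:
        """Total axis length in ns."""
        return self.n_bins * self.bin_width

    def __len__(self) -> int:
        return self.n_bins


def _check_axis_counts(axis: TimeAxis, counts: np.ndarray, what: str) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.shape[0] != axis.n_bins:
        raise ValueError(
            f"{what}: counts must be a 1-D vector of length {axis.n_bins}, "
            f"got shape {counts.shape}"
        )
    if np.any(counts < 0):
        raise ValueError(f"{what}: counts must be non-negative")
    return counts


@dataclass(frozen=True)
class InstrumentResponse:
    """Measured (or simulated) instrument response histogram.

    ``fwhm`` and ``t0`` record the nominal width and peak position used to
    build the profile; ``counts`` is the histogram itself.
    """

    axis: TimeAxis
    counts: np.ndarray
    fwhm: float
    t0: float

    def __post_init__(self) -> None:
        counts = _check_axis_counts(self.axis, np.asarray(self.counts, dtype=float), "IRF")
        if not np.any(counts > 0):
            raise ValueError("IRF must have at least one strictly positive bin")
        object.__setattr__(self, "counts", counts)

    def normalized(self) -> np.ndarray:
        """Unit-sum IRF profile, as required by the reconvolution integral."""
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class DecayTrace:
    """One photon-count decay histogram plus its acquisition metadata.

    Measured (or Poisson-sampled) traces carry integer counts; noise-free
    expected curves keep their float values so exact bilinearity is
    preserved for rank analysis.
    """

    axis: TimeAxis
    counts: np.ndarray
    sequence_id: str = ""
    ph: float = float("nan")
    wavelength: float = float("nan")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        counts = _check_axis_counts(self.axis, counts, "DecayTrace")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if np.array_equal(counts, rounded):
                counts = rounded.astype(np.int64)
        object.__setattr__(self, "counts", counts)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ExponentialModel:
    """Sum-of-exponentials decay law ``sum_i A_i exp(-t / tau_i)``.

    Amplitudes are in counts at time zero (non-negative), lifetimes in ns
    (strictly positive).  Terms are stored in canonical order, descending
    lifetime.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        tau = np.atleast_1d(np.asarray(self.lifetimes, dtype=float))
        if amp.shape != tau.shape or amp.ndim != 1 or amp.size == 0:
            raise ValueError("amplitudes and lifetimes must be 1-D vectors of equal length")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(tau <= 0) or not np.all(np.isfinite(tau)):
            raise ValueError("lifetimes must be strictly positive and finite")
        order = np.argsort(-tau, kind="stable")
        object.__setattr__(self, "amplitudes", amp[order])
        object.__setattr__(self, "lifetimes", tau[order])

    @property
    def n(self) -> int:
        return self.lifetimes.size

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Model intensity at (non-negative) times ``t`` in ns."""
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-t[None, :] / self.lifetimes[:, None]),
            axis=0,
        )

    @property
    def fractional_amplitudes(self) -> np.ndarray:
        """Per-term amplitude percentages summing to 100."""
        total = self.amplitudes.sum()
        if total <= 0:
            raise ValueError("fractional amplitudes undefined for an all-zero model")
        return 100.0 * self.amplitudes / total

    def combine(self, other: "ExponentialModel") -> "ExponentialModel":
        """Union of the terms of two models (amplitudes concatenated)."""
        return ExponentialModel(
            np.concatenate([self.amplitudes, other.amplitudes]),
            np.concatenate([self.lifetimes, other.lifetimes]),
        )

    def scaled(self, factor: float) -> "ExponentialModel":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, amplitudes=self.amplitudes * factor)
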