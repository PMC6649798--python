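"""Synthetic TCSPC datasets with the statistical structure the analysis assumes.

The forward model mirrors the acquisition this package targets: a
Gaussian instrument response of 50 ps FWHM on a 25 ps-per-bin axis,
species defined by sum-of-exponential decay laws mixed bilinearly across
pH, every trace scaled so its expected maximum hits the acquisition stop
level (3x10^4 counts by default) and Poisson counting noise added per
channel.  Seven emission wavelengths (560-610 nm) at pH 7/6/5/4 give the
28-trace series a single DNA beacon sequence produces.

Three named presets provide the study conditions:

``control``
    A polythymidine-like beacon that cannot fold: one pH-invariant
    species with lifetimes 1.88/0.80/0.20 ns.
``short_sequence``
    A 25-nt i-motif beacon: open form dominant at pH 7, one folded
    i-motif species dominant at pH 5-6 and a second at pH 4 (three
    species, sequential logistic transitions).
``long_sequence``
    A 34-nt beacon: a single folded species across pH 4-6 plus the open
    form at pH 7 (two species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .axes import (
    FWHM_TO_SIGMA,
    DecayTrace,
    DegenerateIRFError,
    ExponentialModel,
    InstrumentResponse,
    TimeAxis,
)
from .fitting import reconvolve

__all__ = [
    "SpeciesDefinition",
    "SimulationScenario",
    "make_irf",
    "make_axis",
    "expected_curve",
    "simulate_trace",
    "simulate_ph_series",
    "preset_scenario",
    "PRESET_NAMES",
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_PH_VALUES",
]

DEFAULT_WAVELENGTHS = (560.0, 565.0, 570.0, 575.0, 580.0, 590.0, 610.0)
DEFAULT_PH_VALUES = (4.0, 5.0, 6.0, 7.0)
DEFAULT_PEAK_COUNTS = 30_000
DEFAULT_N_BINS = 500          # 12.5 ns at 25 ps/bin; > 4x the longest lifetime
DEFAULT_IRF_FWHM = 0.050      # ns
DEFAULT_IRF_T0 = 0.5          # ns


@dataclass(frozen=True)
class SpeciesDefinition:
    """One conformer: its decay law and its relative abundance per pH."""

    name: str
    model: ExponentialModel
    concentration_profile: Mapping[float, float]

    def __post_init__(self) -> None:
        for ph, c in self.concentration_profile.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(
                    f"species {self.name!r}: abundance {c} at pH {ph} outside [0, 1]"
                )

    def abundance(self, ph: float) -> float:
        try:
            return self.concentration_profile[ph]
        except KeyError:
            raise KeyError(
                f"species {self.name!r} has no abundance defined at pH {ph}"
            ) from None


@dataclass(frozen=True)
class SimulationScenario:
    """Full description of one simulated pH/wavelength series."""

    species: tuple[SpeciesDefinition, ...]
    ph_values: tuple[float, ...] = DEFAULT_PH_VALUES
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    wavelength_scale: tuple[float, ...] = ()
    peak_counts: int = DEFAULT_PEAK_COUNTS
    seed: int = 0
    sequence_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("need at least one species")
        if not self.ph_values:
            raise ValueError("need at least one pH value")
        scale = self.wavelength_scale or tuple(1.0 for _ in self.wavelengths)
        if len(scale) != len(self.wavelengths):
            raise ValueError("wavelength_scale length must match wavelengths")
        if any(s <= 0 for s in scale):
            raise ValueError("wavelength_scale entries must be positive")
        if self.peak_counts < 1:
            raise ValueError("peak_counts must be >= 1")
        object.__setattr__(self, "wavelength_scale", tuple(scale))
        # fail early on incomplete concentration profiles
        for sp in self.species:
            for ph in self.ph_values:
                sp.abundance(ph)


def make_axis(
    n_bins: int = DEFAULT_N_BINS, bin_width: float = 0.025, origin: float = 0.0
) -> TimeAxis:
    """Default acquisition axis: 500 bins of 25 ps."""
    return TimeAxis(n_bins=n_bins, bin_width=bin_width, origin=origin)


def make_irf(
    fwhm: float = DEFAULT_IRF_FWHM,
    t0: float = DEFAULT_IRF_T0,
    axis: TimeAxis | None = None,
) -> InstrumentResponse:
    """Gaussian IRF of the given FWHM centred at ``t0``, unit sum.

    Raises
    ------
    DegenerateIRFError
        If the axis does not contain ``t0 +- 3 sigma``.
    """
    if axis is None:
        axis = make_axis()
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm * FWHM_TO_SIGMA
    t = axis.centers
    if t0 - 3 * sigma < t[0] - axis.bin_width / 2 or t0 + 3 * sigma > t[-1] + axis.bin_width / 2:
        raise DegenerateIRFError(
            f"axis [{t[0]:.4g}, {t[-1]:.4g}] ns cannot contain the IRF "
            f"t0 +- 3 sigma = {t0:.4g} +- {3 * sigma:.4g} ns"
        )
    profile = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    return InstrumentResponse(axis=axis, counts=profile / profile.sum(), fwhm=fwhm, t0=t0)


def expected_curve(
    species_mixture: Sequence[tuple[SpeciesDefinition, float]],
    irf: InstrumentResponse,
    peak_counts: float,
    scale: float = 1.0,
) -> np.ndarray:
    """Noise-free expected trace of a weighted species mixture.

    The weighted sum of reconvolved species decays is rescaled so its
    maximum equals ``peak_counts`` (the acquisition stop level), then
    multiplied by ``scale`` (relative detection intensity).
    """
    if not species_mixture:
        raise ValueError("empty species mixture")
    weights = np.array([w for _, w in species_mixture], dtype=float)
    if np.any(weights < 0):
        raise ValueError("species weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("species weights must not all be zero")
    curve = np.zeros(irf.axis.n_bins)
    for (sp, w) in species_mixture:
        if w > 0:
            curve += w * reconvolve(irf, sp.model)
    return curve / curve.max() * peak_counts * scale


def simulate_trace(
    species_mixture: Sequence[tuple[SpeciesDefinition, float]],
    irf: InstrumentResponse,
    peak_counts: int = DEFAULT_PEAK_COUNTS,
    seed: int | Sequence[int] | None = 0,
    scale: float = 1.0,
    noise: bool = True,
    sequence_id: str = "",
    ph: float = float("nan"),
    wavelength: float = float("nan"),
) -> DecayTrace:
    """Draw one Poisson-noised decay trace from a species mixture.

    Identical ``seed`` gives an identical trace.  With ``noise=False`` the
    expected curve is rounded to integers instead of sampled.
    """
    mu = expected_curve(species_mixture, irf, peak_counts, scale)
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mu)
    else:
        counts = mu  # exact expected curve; rank/bilinearity preserved
    return DecayTrace(
        axis=irf.axis, counts=counts, sequence_id=sequence_id, ph=ph,
        wavelength=wavelength,
    )


def simulate_ph_series(
    scenario: SimulationScenario,
    irf: InstrumentResponse,
    noise: bool = True,
) -> list[DecayTrace]:
    """One trace per (pH, wavelength) pair of the scenario.

    Per-trace random sub-streams are derived deterministically from
    ``(scenario.seed, pH index, wavelength index)`` so the series does not
    depend on iteration order.
    """
    traces = []
    for i_ph, ph in enumerate(scenario.ph_values):
        mixture = [(sp, sp.abundance(ph)) for sp in scenario.species]
        for i_wl, wl in enumerate(scenario.wavelengths):
            traces.append(
                simulate_trace(
                    mixture,
                    irf,
                    peak_counts=scenario.peak_counts,
                    seed=(scenario.seed, i_ph, i_wl),
                    scale=scenario.wavelength_scale[i_wl],
                    noise=noise,
                    sequence_id=scenario.sequence_id,
                    ph=ph,
                    wavelength=wl,
                )
            )
    return traces


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _logistic_profiles(
    ph_values: Sequence[float], midpoints: Sequence[float], hill: float = 2.0
) -> list[dict[float, float]]:
    """Sequential logistic abundance profiles along pH.

    ``midpoints`` are the transition midpoints ordered from acidic to
    neutral; with k midpoints the function returns k+1 species profiles
    ordered most-acidic first, each a Henderson–Hasselbalch-like sigmoid
    (Hill slope ``hill``) and summing to 1 at every pH.
    """
    mids = sorted(midpoints)
    profiles: list[dict[float, float]] = [dict() for _ in range(len(mids) + 1)]
    for ph in ph_values:
        # f[j] = fraction of population past transition j (toward neutral)
        past = [1.0 / (1.0 + 10.0 ** (hill * (m - ph))) for m in mids]
        prev = 1.0
        fracs = []
        for p in past:
            fracs.append(prev - p if prev > p else 0.0)
            prev = min(prev, p)
        fracs.append(prev)
        total = sum(fracs)
        for j, f in enumerate(fracs):
            profiles[j][ph] = f / total
    return profiles


# Species decay laws used by the presets: lifetimes (ns) and amplitude
# percentages from published global-fit parameter sets for cyanine/dabcyl
# molecular-beacon sequences (open form at pH 7; folded i-motif species at
# acidic pH with a dominant ~30 ps quenched component).
_OPEN_SHORT = ExponentialModel(np.array([38.17, 44.09, 17.75]),
                               np.array([2.34, 1.11, 0.35]))
_IMOTIF_B_SHORT = ExponentialModel(np.array([4.96, 4.17, 13.87, 77.01]),
                                   np.array([3.03, 0.85, 0.18, 0.03]))
_IMOTIF_A_SHORT = ExponentialModel(np.array([1.75, 2.59, 7.93, 87.73]),
                                   np.array([3.01, 0.88, 0.18, 0.03]))
_OPEN_LONG = ExponentialModel(np.array([64.06, 29.39, 6.56]),
                              np.array([2.62, 1.12, 0.24]))
_IMOTIF_LONG = ExponentialModel(np.array([3.39, 3.26, 10.20, 83.16]),
                                np.array([2.69, 0.88, 0.17, 0.03]))
# Control: unfolded polythymidine-like strand; amplitude split chosen so the
# amplitude-weighted mean lifetime is ~0.72 ns, the plateau a control strand
# shows across the whole pH range.
_CONTROL = ExponentialModel(np.array([20.0, 30.0, 50.0]),
                            np.array([1.88, 0.80, 0.20]))

PRESET_NAMES = ("control", "short_sequence", "long_sequence")


def preset_scenario(
    name: str,
    seed: int = 0,
    peak_counts: int = DEFAULT_PEAK_COUNTS,
    ph_values: Sequence[float] = DEFAULT_PH_VALUES,
    wavelengths: Sequence[float] | None = None,
) -> SimulationScenario:
    """Named study-condition presets (see module docstring)."""
    ph_values = tuple(ph_values)
    if name == "control":
        wavelengths = tuple(wavelengths) if wavelengths else (565.0, 580.0, 610.0)
        species = (
            SpeciesDefinition(
                "control-strand", _CONTROL, {ph: 1.0 for ph in ph_values}
            ),
        )
        return SimulationScenario(
            species=species, ph_values=ph_values, wavelengths=wavelengths,
            peak_counts=peak_counts, seed=seed, sequence_id="F-T10",
        )
    wavelengths = tuple(wavelengths) if wavelengths else DEFAULT_WAVELENGTHS
    if name == "short_sequence":
        prof_a, prof_b, prof_open = _logistic_profiles(ph_values, (4.5, 6.5))
        species = (
            SpeciesDefinition("i-motif-A", _IMOTIF_A_SHORT, prof_a),
            SpeciesDefinition("i-motif-B", _IMOTIF_B_SHORT, prof_b),
            SpeciesDefinition("open-form", _OPEN_SHORT, prof_open),
        )
        seq = "F-TT-Q"
    elif name == "long_sequence":
        prof_folded, prof_open = _logistic_profiles(ph_values, (6.5,))
        species = (
            SpeciesDefinition("i-motif", _IMOTIF_LONG, prof_folded),
            SpeciesDefinition("open-form", _OPEN_LONG, prof_open),
        )
        seq = "F-nmyc-Q"
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return SimulationScenario(
        species=species, ph_values=ph_values, wavelengths=wavelengths,
        peak_counts=peak_counts, seed=seed, sequence_id=seq,
    )
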