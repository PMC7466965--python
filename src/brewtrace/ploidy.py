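"""DNA-content and ploidy inference, plus spore viability.

Ploidy is read two ways: from the G1/G2 peaks of a fluorescence density
(relative to a haploid control) and from the modes of the alternate-allele
frequency spectrum (a tetraploid shows peaks near 0.25, 0.5 and 0.75).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from brewtrace.errors import BrewtraceError, SinglePeakError, UndeterminedPloidyError
from brewtrace.types import FluorescenceSample

log = logging.getLogger(__name__)

MAX_PLOIDY = 8


@dataclass
class FrequencySpectrum:
    """Per-site alternate-allele support fractions in (0, 1)."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if ((f <= 0) | (f >= 1)).any():
            raise BrewtraceError("frequencies must exclude 0 and 1 (fixed sites)")
        self.frequencies = f


def cytometry_peaks(
    sample: FluorescenceSample, bandwidth: Optional[float] = None
) -> tuple[float, float]:
    """Locate the G1 and G2 peaks of a fluorescence distribution.

    A Gaussian KDE (Silverman's bandwidth unless given) is evaluated on a
    fine grid; the two highest local maxima are returned with G1 < G2. A
    warning is logged when the G2/G1 ratio falls outside [1.7, 2.3].
    """
    values = sample.values
    if len(values) < 100:
        raise BrewtraceError("need >= 100 cells for peak finding")
    kde = gaussian_kde(values, bw_method=bandwidth if bandwidth else "silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 1024)
    density = kde(grid)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    peak_idx = np.flatnonzero(interior) + 1
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(density))])
    if len(peak_idx) == 1:
        raise SinglePeakError(float(grid[peak_idx[0]]))
    top_two = peak_idx[np.argsort(density[peak_idx])[-2:]]
    g1, g2 = sorted(float(grid[i]) for i in top_two)
    ratio = g2 / g1
    if not 1.7 <= ratio <= 2.3:
        log.warning("G2/G1 peak ratio %.2f outside [1.7, 2.3]", ratio)
        warnings.warn(f"G2/G1 peak ratio {ratio:.2f} outside [1.7, 2.3]")
    return g1, g2


def infer_dna_content(
    sample_g1: float, haploid_control_g1: float
) -> tuple[float, int]:
    """Ploidy estimate as the ratio of G1 peaks to a haploid control."""
    if sample_g1 <= 0 or haploid_control_g1 <= 0:
        raise BrewtraceError("peak positions must be positive")
    estimate = sample_g1 / haploid_control_g1
    return estimate, int(round(estimate))


def allele_frequency_modes(
    spectrum: FrequencySpectrum, grid: float = 0.05
) -> tuple[list[float], int]:
    """Detect frequency modes and the smallest compatible ploidy.

    Frequencies are histogrammed in bins of width ``grid`` centred on
    multiples of ``grid``; modes are local maxima above 50% of the global
    maximum. The inferred ploidy is the smallest integer p such that every
    mode lies within grid/2 of {i/p : 1 <= i <= p-1}.
    """
    freqs = spectrum.frequencies
    if len(freqs) < 500:
        raise BrewtraceError("need >= 500 frequencies for mode detection")
    n_bins = int(round(1.0 / grid)) + 1
    centers = np.arange(n_bins) * grid
    edges = np.concatenate([centers - grid / 2, [centers[-1] + grid / 2]])
    hist, _ = np.histogram(freqs, bins=edges)
    interior = (hist[1:-1] > hist[:-2]) & (hist[1:-1] >= hist[2:])
    candidates = np.flatnonzero(interior) + 1
    # boundary bins can carry a mode too (e.g. a lone peak near 0.05)
    if len(hist) > 1 and hist[0] > hist[1]:
        candidates = np.concatenate([[0], candidates])
    if len(hist) > 1 and hist[-1] > hist[-2]:
        candidates = np.concatenate([candidates, [len(hist) - 1]])
    threshold = 0.5 * hist.max()
    modes = [float(centers[i]) for i in candidates if hist[i] >= threshold]
    if not modes:
        raise UndeterminedPloidyError("no allele-frequency mode detected")
    for p in range(2, MAX_PLOIDY + 1):
        targets = np.array([i / p for i in range(1, p)])
        if all(np.min(np.abs(targets - m)) <= grid / 2 + 1e-12 for m in modes):
            return modes, p
    raise UndeterminedPloidyError(
        f"modes {modes} match no ploidy <= {MAX_PLOIDY}"
    )


def spore_viability(tetrad_colony_counts: Sequence[int]) -> float:
    """Fraction of viable spores: sum(counts) / (4 * n_tetrads)."""
    counts = list(tetrad_colony_counts)
    if not counts:
        raise BrewtraceError("no tetrads dissected")
    if any(c < 0 or c > 4 for c in counts):
        raise BrewtraceError("tetrad colony counts must lie in 0..4")
    return sum(counts) / (4.0 * len(counts))
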