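"""Reverse conservation analysis (RCA).

Locates regions of unusually *low* conservation among close homologs:
per-site conservation scores (S, high = variable) are standardized to mean
0 / SD 1, smoothed with a centered sliding-window average (default n = 7,
the W mean score), and maximal runs with W at or above an intensity
threshold (default 0.5 SD) are called as peaks.  Two profiles on a shared
coordinate frame can be compared to find regions where exactly one clade
is above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .siterates import SiteRateProfile

__all__ = [
    "PeakRegion",
    "RCAProfile",
    "CladeComparison",
    "normalize",
    "window_mean",
    "call_peaks",
    "rca_profile",
    "compare_clade_profiles",
]

_ROMAN = ("I", "IV", "V", "IX", "X", "XL", "L", "XC", "C", "CD", "D", "CM", "M")
_ROMAN_VALS = (1, 4, 5, 9, 10, 40, 50, 90, 100, 400, 500, 900, 1000)


def _roman(n: int) -> str:
    out = []
    for v, sym in sorted(zip(_ROMAN_VALS, _ROMAN), reverse=True):
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


@dataclass
class PeakRegion:
    """A maximal run of positions with W >= intensity threshold."""

    start: int  # 1-based inclusive
    end: int
    max_w: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("peak start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return not (self.end < start or end < self.start)


@dataclass
class RCAProfile:
    positions: np.ndarray       # coordinate frame (1-based)
    z: np.ndarray               # standardized S scores
    w: np.ndarray               # window means
    window_n: int
    intensity: float
    peaks: list[PeakRegion] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        label_at = {}
        for pk in self.peaks:
            for p in range(pk.start, pk.end + 1):
                label_at[p] = pk.label or ""
        with open(path, "w") as fh:
            fh.write("position\tz\tW\tpeak\n")
            for p, z, w in zip(self.positions, self.z, self.w):
                fh.write(f"{p}\t{z:.6g}\t{w:.6g}\t{label_at.get(int(p), '')}\n")


@dataclass
class CladeComparison:
    profile_a: RCAProfile
    profile_b: RCAProfile
    divergent_regions: list[PeakRegion]


def normalize(s) -> np.ndarray:
    """Standardize scores to mean 0 and sample SD 1 (n-1 denominator)."""
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    sd = s.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("zero variance: scores cannot be standardized")
    return (s - s.mean()) / sd


def window_mean(z, n: int = 7, edges: str = "shrink") -> np.ndarray:
    """Centered sliding-window mean.

    ``edges='shrink'`` averages over the window intersected with the
    sequence (every position gets a value); ``edges='nan'`` leaves
    positions whose full window does not fit undefined.
    """
    z = np.asarray(z, dtype=float)
    if n < 1 or n % 2 == 0:
        raise ValueError("window size must be odd and >= 1")
    h = (n - 1) // 2
    out = np.empty_like(z)
    for i in range(z.size):
        lo, hi = max(0, i - h), min(z.size, i + h + 1)
        out[i] = z[lo:hi].mean()
    if edges == "nan":
        out[:h] = np.nan
        if h:
            out[-h:] = np.nan
    elif edges != "shrink":
        raise ValueError("edges must be 'shrink' or 'nan'")
    return out


def call_peaks(w, intensity: float = 0.5, positions=None,
               min_label_length: int = 3) -> list[PeakRegion]:
    """Maximal runs with ``W >= intensity`` (ties at the threshold count).

    Peaks are ordered N->C; peaks spanning at least ``min_label_length``
    positions get Roman-numeral labels (single- and two-residue peaks are
    still reported, unlabelled).
    """
    w = np.asarray(w, dtype=float)
    if positions is None:
        positions = np.arange(1, w.size + 1)
    above = np.where(np.isnan(w), False, w >= intensity)
    peaks: list[PeakRegion] = []
    i = 0
    while i < w.size:
        if above[i]:
            j = i
            while j + 1 < w.size and above[j + 1]:
                j += 1
            peaks.append(PeakRegion(int(positions[i]), int(positions[j]),
                                    float(np.nanmax(w[i : j + 1]))))
            i = j + 1
        else:
            i += 1
    ordinal = 0
    for pk in peaks:
        if pk.length >= min_label_length:
            ordinal += 1
            pk.label = _roman(ordinal)
    return peaks


def rca_profile(
    site_rates: SiteRateProfile,
    window_n: int = 7,
    intensity: float = 0.5,
    use_reference_positions: bool = True,
    edges: str = "shrink",
) -> RCAProfile:
    """Full RCA pipeline from a site-rate profile.

    Normalization precedes windowing.  If the alignment had a reference
    taxon, columns where the reference is gapped are dropped and peaks are
    reported in reference coordinates; otherwise alignment columns are used.
    """
    keep = np.ones(site_rates.rates.size, dtype=bool)
    if use_reference_positions and (site_rates.reference_positions >= 0).any():
        keep = site_rates.reference_positions >= 0
        positions = site_rates.reference_positions[keep]
    else:
        positions = site_rates.columns[keep]
    z = normalize(site_rates.rates[keep])
    w = window_mean(z, window_n, edges=edges)
    peaks = call_peaks(w, intensity, positions)
    return RCAProfile(positions=np.asarray(positions), z=z, w=w,
                      window_n=window_n, intensity=intensity, peaks=peaks)


def compare_clade_profiles(
    a: RCAProfile, b: RCAProfile, intensity: float = 0.5
) -> CladeComparison:
    """Regions where exactly one clade's W mean is at/above threshold."""
    if a.positions.size != b.positions.size or np.any(a.positions != b.positions):
        raise ValueError("profiles are not on the same coordinate frame")
    above_a = a.w >= intensity
    above_b = b.w >= intensity
    xor = above_a ^ above_b
    regions: list[PeakRegion] = []
    i = 0
    n = xor.size
    while i < n:
        if xor[i]:
            j = i
            while j + 1 < n and xor[j + 1]:
                j += 1
            wmax = float(np.nanmax(np.maximum(a.w[i : j + 1], b.w[i : j + 1])))
            regions.append(PeakRegion(int(a.positions[i]), int(a.positions[j]), wmax))
            i = j + 1
        else:
            i += 1
    return CladeComparison(a, b, regions)
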