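"""Linear retention indices from an n-alkane ladder, and identity assignment.

The index of a compound eluting between alkanes C_n and C_{n+1} under a
linear temperature program is the van den Dool & Kratz interpolation

    I = 100·n + 100·(t − t_n) / (t_{n+1} − t_n).

Identity assignment combines the index window with the two spectral gates
used for targeting: DMF > 900 and RMF > 950 against the library reference
spectrum, with an index tolerance of ±10 units by default (±15 is the
documented alternative preset).
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .library import TargetAnalyte
from .peaks import Peak2D
from .similarity import dmf, rmf
from .synthetic import simulate_spectrum


class IndexOutOfRange(ValueError):
    """Retention time outside the calibrated alkane ladder."""


@dataclass(frozen=True)
class AlkaneCalibration:
    """Ordered (carbon number, ¹t_R minutes) calibration points."""

    carbons: tuple[int, ...]
    times: tuple[float, ...]

    def __post_init__(self):
        if len(self.carbons) != len(self.times) or len(self.carbons) < 2:
            raise ValueError("need >= 2 matching calibration points")
        if any(b <= a for a, b in zip(self.carbons, self.carbons[1:])):
            raise ValueError("carbon numbers must increase")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("retention times must increase with carbon number")

    @classmethod
    def from_dict(cls, ladder: dict[int, float]) -> "AlkaneCalibration":
        ns = tuple(sorted(ladder))
        return cls(ns, tuple(ladder[n] for n in ns))

    @classmethod
    def from_csv(cls, path) -> "AlkaneCalibration":
        """Two-column delimited text: carbon_number, rt1_min."""
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh) if r]
        if rows and not rows[0][0].strip().isdigit():
            rows = rows[1:]  # optional header
        return cls.from_dict({int(n): float(t) for n, t in rows})


def retention_index(t: float, cal: AlkaneCalibration) -> float:
    """Linear retention index I^T of an elution time within the ladder.

    A gap in the ladder (e.g. a missing C10) is interpolated across with the
    proportionally larger index span (200 units across a two-carbon gap).

    Raises
    ------
    IndexOutOfRange
        If ``t`` lies outside [t_first, t_last] — the condition the library
        records as 'NC' or '>2500'.
    """
    times = cal.times
    if not (times[0] <= t <= times[-1]):
        raise IndexOutOfRange(
            f"t={t:.3f} min outside ladder [{times[0]:.3f}, {times[-1]:.3f}]")
    i = bisect_right(times, t) - 1
    i = min(i, len(times) - 2)
    n_lo, n_hi = cal.carbons[i], cal.carbons[i + 1]
    t_lo, t_hi = times[i], times[i + 1]
    return 100.0 * n_lo + 100.0 * (n_hi - n_lo) * (t - t_lo) / (t_hi - t_lo)


def calibration_from_peaks(peaks: list[Peak2D], first_carbon: int
                           ) -> AlkaneCalibration:
    """Build a calibration from the detected peaks of an alkane run,
    assigning consecutive carbon numbers in elution order."""
    times = sorted(p.rt1 for p in peaks)
    return AlkaneCalibration(
        tuple(range(first_carbon, first_carbon + len(times))), tuple(times))


def assign_identity(peak: Peak2D, library: list[TargetAnalyte],
                    cal: AlkaneCalibration, dmf_min: float = 900,
                    rmf_min: float = 950, it_tol: float = 10.0
                    ) -> TargetAnalyte | None:
    """Assign a library identity to a peak, or None.

    Candidates must have a numeric experimental index within ``it_tol`` of
    the peak's index, DMF ≥ ``dmf_min`` and RMF ≥ ``rmf_min`` against the
    library reference spectrum.  The highest-DMF candidate wins; ties break
    on smaller index deviation, then on library order.
    """
    try:
        it_peak = retention_index(peak.rt1, cal)
    except IndexOutOfRange:
        return None
    best = None  # (-dmf, deviation, order, analyte)
    for order, analyte in enumerate(library):
        if not analyte.has_numeric_index:
            continue
        dev = abs(it_peak - float(analyte.it_exp))
        if dev > it_tol:
            continue
        ref = simulate_spectrum(analyte.cas)
        d = dmf(peak.apex_spectrum, ref)
        if d < dmf_min:
            continue
        if rmf(peak.apex_spectrum, ref) < rmf_min:
            continue
        key = (-d, dev, order)
        if best is None or key < best[0]:
            best = (key, analyte)
    return None if best is None else best[1]


def write_calibration(cal: AlkaneCalibration, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["carbon_number", "rt1_min"])
        for n, t in zip(cal.carbons, cal.times):
            w.writerow([n, repr(t)])


def index_array(times: np.ndarray, cal: AlkaneCalibration) -> np.ndarray:
    """Vectorized retention_index; NaN where out of range."""
    out = np.full(len(times), np.nan)
    for i, t in enumerate(np.asarray(times, dtype=float)):
        try:
            out[i] = retention_index(t, cal)
        except IndexOutOfRange:
            pass
    return out
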