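"""Spectral match factors on the NIST 0–999 scale.

The direct match factor (DMF) is a weighted squared-cosine between two stick
spectra evaluated over the union of their m/z channels; the reverse match
factor (RMF) evaluates the same statistic restricted to the channels where
the *reference* spectrum has signal, so that extra channels in the analyzed
spectrum (co-elution, background) are not penalised.  Peak weighting follows
the Stein–Scott convention, intensity^0.5 · (m/z)^1 by default; exponents are
configurable because commercial implementations differ.
"""

from __future__ import annotations

import math

import numpy as np

from .chroma import MassSpectrum


def _weighted(spec: MassSpectrum, mz_weight: float, int_power: float) -> np.ndarray:
    dense = spec.to_dense()
    mz = np.arange(dense.size) + 35.0
    return np.power(dense, int_power) * np.power(mz, mz_weight)


def _cosine2_999(a: np.ndarray, b: np.ndarray) -> int:
    na = float(a @ a)
    nb = float(b @ b)
    if na == 0 or nb == 0:
        return 0
    c2 = float(a @ b) ** 2 / (na * nb)
    # round half-up onto the integer 0-999 scale
    return int(math.floor(999.0 * c2 + 0.5))


def dmf(analyzed: MassSpectrum, reference: MassSpectrum,
        mz_weight: float = 1.0, int_power: float = 0.5) -> int:
    """Direct match factor (0–999) between two spectra.

    Returns 0 when the channel supports are disjoint; symmetric in its
    arguments and invariant to intensity rescaling of either spectrum.
    """
    if analyzed.is_empty or reference.is_empty:
        raise ValueError("match factors require non-empty spectra")
    return _cosine2_999(
        _weighted(analyzed, mz_weight, int_power),
        _weighted(reference, mz_weight, int_power),
    )


def rmf(analyzed: MassSpectrum, reference: MassSpectrum,
        mz_weight: float = 1.0, int_power: float = 0.5) -> int:
    """Reverse match factor: DMF restricted to the reference's channels."""
    if analyzed.is_empty or reference.is_empty:
        raise ValueError("match factors require non-empty spectra")
    wa = _weighted(analyzed, mz_weight, int_power)
    wr = _weighted(reference, mz_weight, int_power)
    mask = wr > 0
    return _cosine2_999(wa[mask], wr[mask])


def match_score(analyzed: MassSpectrum, reference: MassSpectrum,
                mz_weight: float = 1.0, int_power: float = 0.5) -> tuple[int, int]:
    """(DMF, RMF) pair for one analyzed-vs-reference comparison."""
    return (dmf(analyzed, reference, mz_weight, int_power),
            rmf(analyzed, reference, mz_weight, int_power))
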