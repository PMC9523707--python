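"""Data model and I/O for GC×GC-TOF MS runs.

A run is a three-dimensional data cube indexed by (modulation, within-period
sample point, nominal m/z channel).  The first axis carries first-dimension
retention time (one modulation every ``p_m`` seconds), the second axis carries
second-dimension retention time (sampled at ``acq_hz``), and the third axis is
a unit-mass m/z grid (35–350, 316 channels).  Summing over the channel axis
yields the total-ion-current (TIC) raster on which 2D peaks are detected.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

MZ_MIN = 35
MZ_MAX = 350
N_CHANNELS = MZ_MAX - MZ_MIN + 1

#: Sample classes of the default silage study design, plus pooled quality
#: controls.  SampleMeta accepts any label so the chemometric layer can be
#: used on arbitrary designs; the simulator emits these six.
CLASS_LABELS = ("herbage_low", "herbage_high", "con", "lbuc", "lpar", "qc")


class FormatError(ValueError):
    """A run container violates the cube/metadata contract."""


@dataclass(frozen=True)
class MassSpectrum:
    """Unit-mass stick spectrum over integer m/z channels in [35, 350]."""

    channels: np.ndarray  # int, strictly increasing
    intensities: np.ndarray  # float, >= 0

    def __post_init__(self):
        ch = np.asarray(self.channels, dtype=int)
        it = np.asarray(self.intensities, dtype=float)
        if ch.ndim != 1 or it.shape != ch.shape:
            raise ValueError("channels and intensities must be matching 1-D arrays")
        if ch.size and (np.any(np.diff(ch) <= 0)):
            raise ValueError("channels must be strictly increasing")
        if ch.size and (ch[0] < MZ_MIN or ch[-1] > MZ_MAX):
            raise ValueError(f"channels must lie within [{MZ_MIN}, {MZ_MAX}]")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "intensities", it)

    @property
    def is_empty(self) -> bool:
        return self.channels.size == 0 or not np.any(self.intensities > 0)

    @property
    def base_peak(self) -> int:
        """m/z of the most intense channel."""
        if self.is_empty:
            raise ValueError("empty spectrum has no base peak")
        return int(self.channels[np.argmax(self.intensities)])

    def to_dense(self) -> np.ndarray:
        """Intensities on the full 316-channel grid (zeros where absent)."""
        dense = np.zeros(N_CHANNELS)
        dense[self.channels - MZ_MIN] = self.intensities
        return dense

    @classmethod
    def from_dense(cls, dense: np.ndarray) -> "MassSpectrum":
        dense = np.asarray(dense, dtype=float)
        idx = np.nonzero(dense > 0)[0]
        return cls(idx + MZ_MIN, dense[idx])

    def scaled(self, top: float = 999.0) -> "MassSpectrum":
        """Rescale so the base peak equals ``top`` (NIST-style presentation)."""
        m = float(np.max(self.intensities))
        if m <= 0:
            raise ValueError("cannot scale an empty spectrum")
        return MassSpectrum(self.channels, self.intensities * (top / m))


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one analytical run within the study design."""

    sample_id: str
    class_label: str
    replicate_id: int
    analytical_replicate: int = 1
    acquisition_order: int = 0

    def __post_init__(self):
        if not self.class_label:
            raise ValueError("class label must be non-empty")


@dataclass
class Chromatogram2D:
    """One GC×GC-TOF MS run: data cube plus acquisition geometry.

    Parameters
    ----------
    cube : ndarray, shape (n_mod, n_pts, n_mz)
        Non-negative detector counts.  ``n_pts`` must equal
        ``round(p_m * acq_hz)`` and ``n_mz`` must be 316 (m/z 35–350).
    p_m : float
        Modulation period in seconds (default 3.5).
    acq_hz : float
        Spectrum acquisition rate in Hz (default 100, so 350 points/period).
    meta : SampleMeta
    """

    cube: np.ndarray
    p_m: float = 3.5
    acq_hz: float = 100.0
    meta: SampleMeta = field(
        default_factory=lambda: SampleMeta("unnamed", "qc", 1)
    )

    def __post_init__(self):
        cube = np.asarray(self.cube)
        if cube.ndim != 3:
            raise FormatError("cube must be 3-D (modulations × points × m/z)")
        n_pts_expected = round(self.p_m * self.acq_hz)
        if cube.shape[1] != n_pts_expected:
            raise FormatError(
                f"cube has {cube.shape[1]} points/period; p_m × acq_hz "
                f"requires {n_pts_expected}"
            )
        if cube.shape[2] != N_CHANNELS:
            raise FormatError(
                f"cube has {cube.shape[2]} m/z channels; expected {N_CHANNELS}"
            )
        if cube.size and float(cube.min()) < 0:
            raise FormatError("cube contains negative counts")
        self.cube = cube

    @property
    def n_mod(self) -> int:
        return self.cube.shape[0]

    @property
    def n_pts(self) -> int:
        return self.cube.shape[1]

    @property
    def mz(self) -> np.ndarray:
        return np.arange(MZ_MIN, MZ_MAX + 1)

    def tic(self) -> np.ndarray:
        """TIC raster: channel-sum of the cube, shape (n_mod, n_pts)."""
        return self.cube.sum(axis=2, dtype=np.float64)

    def spectrum_at(self, mod_index: int, pt_index: int) -> MassSpectrum:
        """Stick spectrum of a single cube point."""
        return MassSpectrum.from_dense(self.cube[mod_index, pt_index, :])

    def run_minutes(self) -> float:
        return self.n_mod * self.p_m / 60.0


def coords_of(point: tuple[int, int], chrom: Chromatogram2D) -> tuple[float, float]:
    """Map a (modulation, point) index pair to (¹t_R minutes, ²t_R seconds).

    ¹t_R = mod_index · p_m / 60;  ²t_R = pt_index / acq_hz (within-period).
    """
    mod_index, pt_index = point
    if not (0 <= mod_index < chrom.n_mod and 0 <= pt_index < chrom.n_pts):
        raise IndexError(f"point {point} outside cube of shape "
                         f"{(chrom.n_mod, chrom.n_pts)}")
    return mod_index * chrom.p_m / 60.0, pt_index / chrom.acq_hz


def indices_of(rt1_min: float, rt2_s: float, chrom: Chromatogram2D) -> tuple[int, int]:
    """Nearest (modulation, point) index for retention coordinates."""
    mod = int(round(rt1_min * 60.0 / chrom.p_m))
    pt = int(round(rt2_s * chrom.acq_hz))
    if not (0 <= mod < chrom.n_mod and 0 <= pt < chrom.n_pts):
        raise IndexError(f"({rt1_min} min, {rt2_s} s) outside run window")
    return mod, pt


# ---------------------------------------------------------------------------
# Run container I/O: a single-file zip holding the cube (npy) and a JSON
# metadata block.  Self-describing and lossless.
# ---------------------------------------------------------------------------

def write_run(chrom: Chromatogram2D, path) -> None:
    """Write a run to a single-file container (cube + geometry + metadata)."""
    meta = {
        "p_m": chrom.p_m,
        "acq_hz": chrom.acq_hz,
        "meta": asdict(chrom.meta),
    }
    # stored (uncompressed) members: detector noise does not compress, and
    # fixed timestamps keep the container byte-deterministic under a seed
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        buf = io.BytesIO()
        np.save(buf, chrom.cube)
        for name, payload in (("cube.npy", buf.getvalue()),
                              ("meta.json", json.dumps(meta))):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, payload)


def read_run(path) -> Chromatogram2D:
    """Read a run container written by :func:`write_run`.

    Raises
    ------
    FormatError
        If the container misses a required member or violates a cube
        invariant (shape mismatch, negative counts).
    """
    with zipfile.ZipFile(path, "r") as zf:
        names = set(zf.namelist())
        if "cube.npy" not in names or "meta.json" not in names:
            raise FormatError("container must hold 'cube.npy' and 'meta.json'")
        cube = np.load(io.BytesIO(zf.read("cube.npy")))
        meta = json.loads(zf.read("meta.json"))
    for key in ("p_m", "acq_hz", "meta"):
        if key not in meta:
            raise FormatError(f"metadata block missing {key!r}")
    return Chromatogram2D(
        cube=cube,
        p_m=float(meta["p_m"]),
        acq_hz=float(meta["acq_hz"]),
        meta=SampleMeta(**meta["meta"]),
    )


def export_tic(chrom: Chromatogram2D, path) -> None:
    """Export the TIC raster as delimited text (one row per modulation)."""
    np.savetxt(path, chrom.tic(), delimiter="\t", fmt="%.6g")
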