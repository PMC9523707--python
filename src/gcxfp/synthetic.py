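"""Seeded synthetic GC×GC-TOF MS studies with the statistical structure the
fingerprinting analysis assumes.

No raw chromatograms of the silage study are publicly deposited, so this
module stands in for the instrument: it plants library analytes as separable
2D Gaussians on the retention plane, gives every compound a deterministic
reference stick spectrum, applies class-specific fold-changes, multiplicative
log-normal response noise, retention jitter at the reported %RSD scales, two
preloaded internal standards, additive detector baseline noise, and pooled
quality-control (QC) runs.  Every stage of the downstream pipeline is thereby
testable offline against known ground truth.

Retention jitter is decomposed into a shared per-run drift (a single
multiplicative factor per dimension per run) plus a smaller independent
per-peak residual; the two components sum in variance to the configured
relative SDs (defaults 0.79% for ¹t_R, 4.09% for ²t_R).  Run-to-run drift in
temperature-programmed GC is predominantly systematic, which is what makes
template-based realignment effective; a purely independent per-peak jitter at
the same total scale would not be correctable by any retention transform.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .chroma import (
    MZ_MIN, MZ_MAX, N_CHANNELS, Chromatogram2D, MassSpectrum, SampleMeta,
)
from .library import TargetAnalyte, load_library, by_name


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string-able parts."""
    text = "|".join(str(p) for p in parts)
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Reference spectra
# ---------------------------------------------------------------------------

def simulate_spectrum(cas: str, seed_base: int = 0) -> MassSpectrum:
    """Deterministic synthetic stick spectrum for a compound key.

    Stands in for a database reference spectrum: 8–20 channels drawn from the
    unit-mass 35–350 grid, base peak scaled to 999.  The spectrum depends only
    on ``hash(cas, seed_base)``, so identification tests are reproducible,
    and distinct keys give near-orthogonal spectra with high probability.
    """
    if not cas:
        raise ValueError("compound key must be non-empty")
    rng = np.random.default_rng(_stable_seed("spectrum", cas, seed_base))
    n = int(rng.integers(8, 21))
    channels = np.sort(rng.choice(np.arange(MZ_MIN, MZ_MAX + 1), size=n, replace=False))
    intensities = rng.uniform(30.0, 999.0, size=n)
    return MassSpectrum(channels, intensities).scaled(999.0)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InternalStandard:
    """Preloaded internal standard: fixed position and nominal volume."""

    name: str
    rt1_min: float
    rt2_s: float
    volume: float = 1.0e7

    @property
    def spectrum(self) -> MassSpectrum:
        return simulate_spectrum(f"IS:{self.name}")


@dataclass(frozen=True)
class PlantedCompound:
    """One compound planted in simulated runs.

    ``classes_present`` restricts the compound to a subset of classes (used
    for class-specific unknowns); None means present everywhere.
    """

    name: str
    cas: str
    rt1_min: float
    rt2_s: float
    base_volume: float
    library_entry: TargetAnalyte | None = None
    classes_present: tuple[str, ...] | None = None

    @property
    def spectrum(self) -> MassSpectrum:
        return simulate_spectrum(self.cas)


@dataclass
class NoiseModel:
    """Detector-noise parameters.

    baseline_mean/sd: additive Gaussian baseline per cube point, truncated at
    zero (counts are non-negative).  response_rsd: SD of the multiplicative
    log-normal factor applied to every planted peak volume (the reported mean
    response %RSD of ~12.5% motivates the 0.12 default).
    """

    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    response_rsd: float = 0.12


@dataclass
class StudyDesign:
    """Layout and noise model of a simulated fingerprinting study.

    The default design mirrors the silage experiment: five sample classes
    (herbage at two dry-matter levels, uninoculated control CON, and two
    inoculated treatments Lbuc / Lpar) plus pooled QC mixtures, 35 runs in
    total including analytical duplicates.
    """

    analytes: list[PlantedCompound]
    class_replicates: dict[str, int] = field(default_factory=lambda: {
        "herbage_low": 3, "herbage_high": 3,
        "con": 6, "lbuc": 6, "lpar": 6, "qc": 6,
    })
    #: classes receiving one extra analytical duplicate of biological rep 1
    analytical_duplicates: tuple[str, ...] = (
        "herbage_low", "herbage_high", "con", "lbuc", "lpar",
    )
    #: class -> analyte-name -> multiplicative fold-change (default 1.0)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: QC runs are expectation-averages of these parent classes
    qc_parents: tuple[str, ...] = ("con",)
    internal_standards: tuple[InternalStandard, InternalStandard] = (
        InternalStandard("alpha/beta-thujone", 13.40, 1.95),
        InternalStandard("methyl 2-octynoate", 21.30, 1.85),
    )
    rt_jitter: tuple[float, float] = (0.0079, 0.0409)  # relative SD, rt1 / rt2
    jitter_systematic_frac: float = 0.9  # fraction of jitter *variance* shared per run
    noise: NoiseModel = field(default_factory=NoiseModel)
    peak_sigma: tuple[float, float] = (2.5, 0.06)  # modulations, seconds
    run_minutes: float = 30.0
    p_m: float = 3.5
    acq_hz: float = 100.0
    seed: int = 0

    def __post_init__(self):
        for cls, per in self.effects.items():
            for name, f in per.items():
                if not f > 0:
                    raise ValueError(f"fold-change must be positive ({cls}/{name})")
        from .chroma import CLASS_LABELS as _labels
        for cls, n in self.class_replicates.items():
            if cls not in _labels:
                raise ValueError(f"unknown sample class {cls!r}")
            if n < 1:
                raise ValueError("replicate counts must be >= 1")

    # -- derived -----------------------------------------------------------
    @property
    def n_mod(self) -> int:
        return int(round(self.run_minutes * 60.0 / self.p_m))

    def effect(self, class_label: str, analyte_name: str) -> float:
        return self.effects.get(class_label, {}).get(analyte_name, 1.0)

    def expected_volume(self, class_label: str, compound: PlantedCompound) -> float:
        """Noise-free expected 2D peak volume of a compound in a class."""
        if compound.classes_present is not None and \
                class_label not in compound.classes_present:
            return 0.0
        if class_label == "qc":
            return float(np.mean([
                self.expected_volume(p, compound) for p in self.qc_parents
            ]))
        return compound.base_volume * self.effect(class_label, compound.name)

    def sample_metas(self) -> list[SampleMeta]:
        """All runs of the study in seed-randomized acquisition order."""
        metas = []
        for cls, n in self.class_replicates.items():
            for rep in range(1, n + 1):
                metas.append(SampleMeta(f"{cls}-{rep}", cls, rep, 1))
        for cls in self.analytical_duplicates:
            metas.append(SampleMeta(f"{cls}-1b", cls, 1, 2))
        order = np.random.default_rng(
            _stable_seed("run-order", self.seed)).permutation(len(metas))
        return [
            replace(metas[j], acquisition_order=i)
            for i, j in enumerate(order)
        ]


# ---------------------------------------------------------------------------
# Run simulation
# ---------------------------------------------------------------------------

def _add_gaussian(cube: np.ndarray, mu_mod: float, mu_pt: float,
                  sigma_mod: float, sigma_pt: float, volume: float,
                  spectrum: MassSpectrum) -> None:
    """Superpose one separable 2D Gaussian peak, spectrum-resolved."""
    n_mod, n_pts, _ = cube.shape
    lo_m = max(0, int(math.floor(mu_mod - 4.5 * sigma_mod)))
    hi_m = min(n_mod, int(math.ceil(mu_mod + 4.5 * sigma_mod)) + 1)
    lo_p = max(0, int(math.floor(mu_pt - 4.5 * sigma_pt)))
    hi_p = min(n_pts, int(math.ceil(mu_pt + 4.5 * sigma_pt)) + 1)
    if lo_m >= hi_m or lo_p >= hi_p:
        return
    gm = np.exp(-0.5 * ((np.arange(lo_m, hi_m) - mu_mod) / sigma_mod) ** 2)
    gp = np.exp(-0.5 * ((np.arange(lo_p, hi_p) - mu_pt) / sigma_pt) ** 2)
    g = np.outer(gm, gp)
    g *= volume / g.sum()
    frac = spectrum.to_dense()
    frac = frac / frac.sum()
    ch = np.nonzero(frac)[0]
    cube[lo_m:hi_m, lo_p:hi_p, ch] += (
        g[:, :, None] * frac[ch][None, None, :]
    ).astype(cube.dtype)


def simulate_run(design: StudyDesign, class_label: str, replicate: int,
                 analytical_replicate: int = 1) -> Chromatogram2D:
    """Simulate one run of the study; byte-identical for identical seeds.

    Each planted compound is a separable 2D Gaussian whose integrated volume
    equals base × class fold-change × log-normal noise, with every cube point
    spectrally proportional to the compound's reference spectrum.  Internal
    standards and truncated-Gaussian baseline noise are added, and retention
    centers are jittered (shared drift + per-peak residual).
    """
    rng = np.random.default_rng(_stable_seed(
        "run", design.seed, class_label, replicate, analytical_replicate))
    n_pts = int(round(design.p_m * design.acq_hz))
    cube = np.zeros((design.n_mod, n_pts, N_CHANNELS), dtype=np.float32)

    s1, s2 = design.rt_jitter
    fsys = math.sqrt(design.jitter_systematic_frac)
    fres = math.sqrt(1.0 - design.jitter_systematic_frac)
    drift1 = rng.normal(0.0, s1 * fsys)
    drift2 = rng.normal(0.0, s2 * fsys)

    sig_mod, sig2_s = design.peak_sigma
    sig_pt = sig2_s * design.acq_hz

    placed: dict[tuple[int, int], str] = {}
    compounds = list(design.analytes)
    for item in compounds:
        v_exp = design.expected_volume(class_label, item)
        if v_exp <= 0:
            continue
        volume = v_exp * math.exp(rng.normal(0.0, design.noise.response_rsd))
        rt1 = item.rt1_min * (1.0 + drift1 + rng.normal(0.0, s1 * fres))
        rt2 = item.rt2_s * (1.0 + drift2 + rng.normal(0.0, s2 * fres))
        mu_mod = rt1 * 60.0 / design.p_m
        mu_pt = rt2 * design.acq_hz
        key = (int(round(mu_mod)), int(round(mu_pt)))
        if key in placed:
            warnings.warn(
                f"{item.name} and {placed[key]} overlap at {key}; "
                "volumes superpose")
        placed[key] = item.name
        _add_gaussian(cube, mu_mod, mu_pt, sig_mod, sig_pt, volume, item.spectrum)

    for std in design.internal_standards:
        volume = std.volume * math.exp(rng.normal(0.0, design.noise.response_rsd))
        rt1 = std.rt1_min * (1.0 + drift1 + rng.normal(0.0, s1 * fres))
        rt2 = std.rt2_s * (1.0 + drift2 + rng.normal(0.0, s2 * fres))
        _add_gaussian(cube, rt1 * 60.0 / design.p_m, rt2 * design.acq_hz,
                      sig_mod, sig_pt, volume, std.spectrum)

    base = rng.standard_normal(cube.shape, dtype=np.float32)
    base *= design.noise.baseline_sd
    base += design.noise.baseline_mean
    np.clip(base, 0.0, None, out=base)
    cube += base

    meta = SampleMeta(
        sample_id=f"{class_label}-{replicate}" + ("b" if analytical_replicate > 1 else ""),
        class_label=class_label, replicate_id=replicate,
        analytical_replicate=analytical_replicate,
    )
    return Chromatogram2D(cube=cube, p_m=design.p_m, acq_hz=design.acq_hz, meta=meta)


def simulate_study(design: StudyDesign):
    """Yield all runs of the study in acquisition order (lazy: one cube in
    memory at a time).  Metadata order is deterministic under the seed."""
    for meta in design.sample_metas():
        yield simulate_run(design, meta.class_label, meta.replicate_id,
                           meta.analytical_replicate)


def simulate_alkane_run(alkanes: dict[int, float], design: StudyDesign | None = None,
                        rt2_s: float = 2.0, volume: float = 5.0e6) -> Chromatogram2D:
    """Simulate the n-alkane calibration run (one peak per carbon number).

    ``alkanes`` maps carbon number to ¹t_R in minutes; times must increase
    strictly with carbon number.  The run is noise-jitter-free apart from
    detector baseline, as befits a standards injection.
    """
    if not alkanes:
        raise ValueError("alkane map must not be empty")
    ns = sorted(alkanes)
    times = [alkanes[n] for n in ns]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("alkane retention times must increase with carbon number")
    base_design = design or StudyDesign(analytes=[], seed=0)
    run_minutes = max(times) + 1.5
    n_mod = int(round(run_minutes * 60.0 / base_design.p_m))
    n_pts = int(round(base_design.p_m * base_design.acq_hz))
    cube = np.zeros((n_mod, n_pts, N_CHANNELS), dtype=np.float32)
    sig_mod, sig2_s = base_design.peak_sigma
    for n in ns:
        _add_gaussian(cube, alkanes[n] * 60.0 / base_design.p_m,
                      rt2_s * base_design.acq_hz, sig_mod,
                      sig2_s * base_design.acq_hz, volume,
                      simulate_spectrum(f"alkane-C{n}"))
    rng = np.random.default_rng(_stable_seed("alkane-run", base_design.seed))
    base = rng.standard_normal(cube.shape, dtype=np.float32)
    base *= base_design.noise.baseline_sd
    base += base_design.noise.baseline_mean
    np.clip(base, 0.0, None, out=base)
    cube += base
    meta = SampleMeta("alkane-ladder", "qc", 1)
    return Chromatogram2D(cube=cube, p_m=base_design.p_m,
                          acq_hz=base_design.acq_hz, meta=meta)


# ---------------------------------------------------------------------------
# Default alkane ladder, panel and effect matrix
# ---------------------------------------------------------------------------

_ALKANE_ROWS = {
    9: "Nonane", 11: "Undecane", 12: "Dodecane", 13: "Tridecane",
    14: "Tetradecane", 15: "Pentadecane", 16: "Hexadecane",
}


def default_alkane_ladder(library: list[TargetAnalyte] | None = None
                          ) -> dict[int, float]:
    """C9–C25 ladder of ¹t_R values consistent with the packaged library.

    C9 and C11–C16 come from the library's own n-alkane rows.  C10 (absent
    from the library) is solved as the median time that reproduces the
    experimental indices of compounds eluting between C9 and C11.  C17–C25
    are anchored by local linear regressions of ¹t_R on experimental index
    over library compounds near each century mark.
    """
    lib = library if library is not None else load_library()
    ladder = {n: by_name(lib, name).rt1_min for n, name in _ALKANE_ROWS.items()}

    pairs = [(float(a.it_exp), a.rt1_min) for a in lib
             if a.has_numeric_index and a.chem_class != "hydrocarbons"]

    # C10 from compounds bracketed by C9/C11
    t9, t11 = ladder[9], ladder[11]
    estimates = []
    for it, t in pairs:
        if 920 <= it <= 995:
            estimates.append(t9 + 100.0 * (t - t9) / (it - 900.0))
        elif 1005 <= it <= 1080:
            w = (it - 1000.0) / 100.0
            estimates.append((t - w * t11) / (1.0 - w))
    ladder[10] = float(np.median(estimates))

    # C17-C25 by local regression of t on index
    for n in range(17, 26):
        target = 100.0 * n
        for half_width in (80.0, 150.0, 300.0):
            near = [(it, t) for it, t in pairs if abs(it - target) <= half_width]
            if len(near) >= 2 and len({it for it, _ in near}) >= 2:
                break
        its = np.array([it for it, _ in near])
        ts = np.array([t for _, t in near])
        slope, intercept = np.polyfit(its, ts, 1)
        ladder[n] = float(slope * target + intercept)

    # enforce strict monotonicity
    times = [ladder[n] for n in sorted(ladder)]
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + 1e-3
    return dict(zip(sorted(ladder), times))


#: Curated 40-analyte panel spanning all ten chemical classes, including
#: propionic acid, 1-propanol and their esters so the Lpar signature of the
#: silage study can be planted.  All members elute before 30 min and are
#: mutually resolved at the default peak widths.
DEFAULT_PANEL_NAMES = (
    # alcohols
    "Ethanol", "1-Propanol", "2-Methyl-1-propanol (isobutanol)",
    "3-Methyl-2-butanol", "1-Butanol", "4-Heptanol", "(E)-2-Penten-1-ol",
    # acids
    "Acetic acid", "Propionic acid", "Isobutyric acid", "Isovaleric acid",
    # esters
    "Ethyl propionate", "Propyl propionate", "Propyl isovalerate",
    "Isoamyl propionate", "Propyl hexanoate",
    "Propanoic acid, 2-hydroxy-, ethyl ester (ethyl lactate)",
    "Ethyl 2-hexenoate", "Heptyl acetate", "Butyl-(Z)-3-hexenoate",
    # aldehydes
    "3-Methylbutanal", "Hexanal", "(Z)-3-Hexenal", "3-Methyl-2-butenal",
    "(E)-2-Heptenal",
    # aromatics
    "Ethylbenzene", "o-Xylene", "Benzaldehyde",
    # ketones
    "Butanedione", "2-Methyl-3-pentanone", "2,3-Pentanedione",
    # heterocyclic
    "2-Pentylfuran", "2-Furanmethanol (furfuryl alcohol)",
    # hydrocarbons
    "(E)-1,3-Octadiene", "Undecane",
    # others
    "Styrene", "Hexanenitrile",
    # terpenes
    "β-Ocimene", "p-Cymene", "cis-Linalool oxide (furanoid)",
)

#: Class fold-changes relative to herbage (= 1.0), mirroring the reported
#: silage signatures: the Lpar treatment dominated by propionic acid (46-fold
#: over herbage; 8-fold over CON), 1-propanol and propionate esters; ethyl
#: esters and acetates up in all fermented classes; lipoxygenase-derived C6
#: aldehydes depleted by fermentation.
_ETHYL_LACTATE = "Propanoic acid, 2-hydroxy-, ethyl ester (ethyl lactate)"
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "con": {
        "Propionic acid": 5.75, "1-Propanol": 1.5, "Ethanol": 8.0,
        "Acetic acid": 5.0, "Ethyl propionate": 2.0,
        "Propyl propionate": 1.5, "Isoamyl propionate": 2.0,
        "Propyl isovalerate": 2.0, _ETHYL_LACTATE: 3.0,
        "2-Furanmethanol (furfuryl alcohol)": 3.0, "3-Methyl-2-butanol": 1.5,
        "Hexanal": 0.35, "(Z)-3-Hexenal": 0.35, "(E)-2-Heptenal": 0.5,
    },
    "lbuc": {
        "Propionic acid": 18.0, "1-Propanol": 3.0, "Ethanol": 9.0,
        "Acetic acid": 8.0, "Ethyl propionate": 6.0,
        "Propyl propionate": 4.0, "Isoamyl propionate": 5.0,
        "Propyl isovalerate": 4.0, _ETHYL_LACTATE: 6.0,
        "Heptyl acetate": 4.0,
        "2-Furanmethanol (furfuryl alcohol)": 5.0, "3-Methyl-2-butanol": 2.5,
        "Hexanal": 0.35, "(Z)-3-Hexenal": 0.35, "(E)-2-Heptenal": 0.5,
    },
    "lpar": {
        "Propionic acid": 46.0, "1-Propanol": 9.0, "Ethanol": 10.0,
        "Acetic acid": 12.0, "Ethyl propionate": 20.0,
        "Propyl propionate": 18.0, "Isoamyl propionate": 45.0,
        "Propyl isovalerate": 12.0, _ETHYL_LACTATE: 10.0,
        "2-Furanmethanol (furfuryl alcohol)": 15.0, "3-Methyl-2-butanol": 4.0,
        "Butanedione": 3.0, "Isovaleric acid": 5.0,
        "Hexanal": 0.35, "(Z)-3-Hexenal": 0.35, "(E)-2-Heptenal": 0.5,
    },
}


def default_panel(library: list[TargetAnalyte] | None = None,
                  base_volume_range: tuple[float, float] = (2.0e6, 2.0e7),
                  seed: int = 0) -> list[PlantedCompound]:
    """The documented 40-analyte panel with seeded per-analyte base volumes."""
    lib = library if library is not None else load_library()
    rng = np.random.default_rng(_stable_seed("panel-volumes", seed))
    lo, hi = base_volume_range
    panel = []
    for name in DEFAULT_PANEL_NAMES:
        entry = by_name(lib, name)
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        panel.append(PlantedCompound(
            name=entry.name, cas=entry.cas, rt1_min=entry.rt1_min,
            rt2_s=entry.rt2_s, base_volume=base, library_entry=entry,
        ))
    return panel


def default_unknowns() -> list[PlantedCompound]:
    """Non-library compounds planted so untargeted features exist.

    Three are present in every class (they become reliable template peaks
    without identity); one is Lpar-specific and therefore surfaces only as a
    peak-region feature of the composite chromatogram.
    """
    return [
        PlantedCompound("unknown-1", "10000-00-1", 10.90, 2.60, 6.0e6),
        PlantedCompound("unknown-2", "10000-00-2", 19.55, 1.72, 4.0e6),
        PlantedCompound("unknown-3", "10000-00-3", 26.80, 2.10, 8.0e6),
        PlantedCompound("unknown-lpar", "10000-00-4", 16.15, 2.85, 7.0e6,
                        classes_present=("lpar",)),
    ]


def default_design(seed: int = 0,
                   library: list[TargetAnalyte] | None = None) -> StudyDesign:
    """The full default study: 35 runs, 40-analyte panel, 4 unknowns,
    class effects mirroring the silage signatures."""
    lib = library if library is not None else load_library()
    analytes = default_panel(lib, seed=seed) + default_unknowns()
    return StudyDesign(analytes=analytes, effects=DEFAULT_EFFECTS, seed=seed)
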