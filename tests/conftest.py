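import warnings

import numpy as np
import pytest

import gcxfp as g
from gcxfp.align import ProcessedRun

# the packaged table legitimately shares one CAS between two isomer rows
warnings.filterwarnings("ignore", message="CAS 30086-02-3")


@pytest.fixture(scope="session")
def library():
    return g.load_library()


@pytest.fixture(scope="session")
def ladder(library):
    return g.default_alkane_ladder(library)


@pytest.fixture(scope="session")
def calibration(ladder):
    return g.AlkaneCalibration.from_dict(ladder)


def small_design(analyte_names, library, seed=0, run_minutes=12.0,
                 classes=None, effects=None, **kw):
    """Compact study design for fast closed-loop tests: short run window,
    early-eluting analytes, internal standards moved inside the window."""
    analytes = []
    for name in analyte_names:
        a = g.by_name(library, name)
        analytes.append(g.PlantedCompound(
            name=a.name, cas=a.cas, rt1_min=a.rt1_min, rt2_s=a.rt2_s,
            base_volume=5.0e6, library_entry=a))
    return g.StudyDesign(
        analytes=analytes,
        class_replicates=classes or {"herbage_low": 2, "con": 2, "lpar": 2,
                                     "qc": 1},
        analytical_duplicates=(),
        effects=effects or {},
        internal_standards=(
            g.InternalStandard("is-a", 5.00, 1.20),
            g.InternalStandard("is-b", 9.50, 1.60),
        ),
        run_minutes=run_minutes, seed=seed, **kw)


@pytest.fixture(scope="session")
def full_study(library, ladder):
    """The complete default study processed end to end once per session:
    35 simulated runs, detection, alkane calibration, template alignment,
    feature table with identities.  Shared by the closed-loop tests."""
    design = g.default_design(seed=1, library=library)
    runs = [ProcessedRun.from_chromatogram(chrom)
            for chrom in g.simulate_study(design)]
    alk_peaks = g.detect_peaks(g.simulate_alkane_run(ladder, design))
    cal = g.calibration_from_peaks(alk_peaks, first_carbon=9)
    table, template = g.fingerprint_study(
        runs,
        internal_standards=[(s.name, s.rt1_min, s.rt2_s)
                            for s in design.internal_standards],
        library=library, cal=cal)
    return {"design": design, "runs": runs, "cal": cal,
            "table": table, "template": template}


def make_raster(shape=(80, 60), baseline=100.0, noise_sd=5.0, seed=0,
                peaks=()):
    """Raster with optional planted separable Gaussians.

    peaks: iterables of (row, col, sigma_r, sigma_c, volume).
    """
    rng = np.random.default_rng(seed)
    r = rng.normal(baseline, noise_sd, size=shape)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for (pr, pc, sr, sc, vol) in peaks:
        gauss = np.exp(-0.5 * (((rows - pr) / sr) ** 2 + ((cols - pc) / sc) ** 2))
        r += vol * gauss / gauss.sum()
    return r
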