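"""Template-based alignment and UT (untargeted + targeted) fingerprinting.

The cross-run correspondence problem is solved by *template matching*: a
template of expected 2D peaks (retention coordinates + reference spectrum) is
matched against each run's detected peaks under a retention search window and
spectral-similarity gates (DMF and RMF ≥ 750), a low-order retention-plane
transform is fitted per run, and *reliable* peaks — those positively matched
in all but one of the runs — are retained.  Aligned TIC rasters are averaged
into a composite chromatogram from which peak-region features are delineated;
template peaks plus uncovered regions form the UT feature table, with
responses normalised against the two preloaded internal standards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .chroma import Chromatogram2D, MassSpectrum, SampleMeta
from .library import TargetAnalyte
from .peaks import Peak2D, estimate_noise, detect_peaks
from .rindex import AlkaneCalibration, assign_identity
from .similarity import rmf

DEFAULT_WINDOW = (0.30, 0.20)   # ± minutes, ± seconds
DEFAULT_GATE = 750              # DMF and RMF floor for a positive match


# ---------------------------------------------------------------------------
# Retention-plane transform: degree-2 polynomial in rt1, degree-1 in rt2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetentionTransform:
    """Maps template-frame retention coordinates into one run's frame."""

    coef1: tuple[float, ...] = (0.0, 1.0, 0.0)  # rt1' = c0 + c1·t1 + c2·t1²
    coef2: tuple[float, ...] = (0.0, 1.0)       # rt2' = c0 + c1·t2

    def apply(self, rt1, rt2):
        rt1 = np.asarray(rt1, dtype=float)
        rt2 = np.asarray(rt2, dtype=float)
        c = self.coef1
        d = self.coef2
        return c[0] + c[1] * rt1 + c[2] * rt1 ** 2, d[0] + d[1] * rt2

    @staticmethod
    def identity() -> "RetentionTransform":
        return RetentionTransform()

    @staticmethod
    def fit(src1, src2, dst1, dst2) -> "RetentionTransform":
        """Least-squares fit with one robust reweighting pass (residuals
        beyond 3×MAD are dropped, tolerating ≲10% mismatches)."""
        src1, src2 = np.asarray(src1, float), np.asarray(src2, float)
        dst1, dst2 = np.asarray(dst1, float), np.asarray(dst2, float)

        def _fit1(x, y, deg):
            if len(np.unique(x)) <= deg:
                deg = max(1, len(np.unique(x)) - 1)
            p = np.polyfit(x, y, deg)
            return np.concatenate([p[::-1], np.zeros(3 - len(p))])[:3]

        if src1.size < 3:
            return RetentionTransform.identity()

        def _robust(x, y, deg, ncoef):
            p = _fit1(x, y, deg)
            resid = y - (p[0] + p[1] * x + p[2] * x ** 2)
            mad = np.median(np.abs(resid - np.median(resid)))
            if mad > 0:
                keep = np.abs(resid - np.median(resid)) <= 3 * 1.4826 * mad
                if keep.sum() >= max(ncoef + 1, int(0.5 * len(x))):
                    p = _fit1(x[keep], y[keep], deg)
            return p

        c1 = _robust(src1, dst1, 2, 3)
        c2 = _robust(src2, dst2, 1, 2)[:2]
        return RetentionTransform(tuple(c1), tuple(c2))


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

@dataclass
class TemplateEntry:
    rt1: float
    rt2: float
    spectrum: MassSpectrum
    identity: TargetAnalyte | None = None
    presence: int = 0
    entry_id: int = -1


@dataclass
class Template:
    """Reliable-peak template plus matching constraints."""

    entries: list[TemplateEntry]
    window: tuple[float, float] = DEFAULT_WINDOW
    dmf_min: int = DEFAULT_GATE
    rmf_min: int = DEFAULT_GATE
    n_source_runs: int = 0

    def coords(self) -> np.ndarray:
        return np.array([(e.rt1, e.rt2) for e in self.entries], dtype=float)


@dataclass
class RunAlignment:
    """Per-run outcome of template matching."""

    matches: dict[int, Peak2D | None]        # entry index -> matched peak
    transform: RetentionTransform
    inverse: RetentionTransform


def _weighted_unit(spectra: list[MassSpectrum]) -> np.ndarray:
    """Rows: Stein-Scott weighted, unit-normalised dense spectra."""
    mz = np.arange(35.0, 351.0)
    out = np.zeros((len(spectra), mz.size))
    for i, s in enumerate(spectra):
        w = np.sqrt(s.to_dense()) * mz
        n = np.linalg.norm(w)
        if n > 0:
            out[i] = w / n
    return out


def match_peaks(template: Template, peaks: list[Peak2D],
                transform: RetentionTransform | None = None
                ) -> dict[int, Peak2D | None]:
    """Greedy one-to-one matching of template entries to one run's peaks.

    Candidates lie inside the retention search window around the
    (transformed) expected coordinates and must pass DMF ≥ 750 and
    RMF ≥ 750 between the entry's reference spectrum and the peak's apex
    spectrum; assignment proceeds in descending DMF and each peak is used
    at most once.
    """
    tr = transform or RetentionTransform.identity()
    matches: dict[int, Peak2D | None] = {i: None for i in range(len(template.entries))}
    if not peaks or not template.entries:
        return matches
    exp1, exp2 = tr.apply(*template.coords().T)
    pk1 = np.array([p.rt1 for p in peaks])
    pk2 = np.array([p.rt2 for p in peaks])
    w1, w2 = template.window

    u_ref = _weighted_unit([e.spectrum for e in template.entries])
    u_pk = _weighted_unit([p.apex_spectrum for p in peaks])
    cos2 = np.clip(u_ref @ u_pk.T, 0.0, 1.0) ** 2
    dmf_mat = np.floor(999.0 * cos2 + 0.5).astype(int)

    in_window = (np.abs(exp1[:, None] - pk1[None, :]) <= w1) & \
                (np.abs(exp2[:, None] - pk2[None, :]) <= w2)
    cand = np.argwhere(in_window & (dmf_mat >= template.dmf_min))
    order = np.argsort(-dmf_mat[cand[:, 0], cand[:, 1]], kind="stable")
    used_entries: set[int] = set()
    used_peaks: set[int] = set()
    for ei, pj in cand[order]:
        ei, pj = int(ei), int(pj)
        if ei in used_entries or pj in used_peaks:
            continue
        if rmf(peaks[pj].apex_spectrum, template.entries[ei].spectrum) < template.rmf_min:
            continue
        matches[ei] = peaks[pj]
        used_entries.add(ei)
        used_peaks.add(pj)
    return matches


def _fit_alignment(template: Template, peaks: list[Peak2D]) -> RunAlignment:
    """Match → fit transform → re-match with the fitted transform."""
    matches = match_peaks(template, peaks)
    pairs = [(template.entries[i], p) for i, p in matches.items() if p is not None]
    tr = RetentionTransform.identity()
    inv = RetentionTransform.identity()
    if len(pairs) >= 3:
        t1 = [e.rt1 for e, _ in pairs]
        t2 = [e.rt2 for e, _ in pairs]
        r1 = [p.rt1 for _, p in pairs]
        r2 = [p.rt2 for _, p in pairs]
        tr = RetentionTransform.fit(t1, t2, r1, r2)
        inv = RetentionTransform.fit(r1, r2, t1, t2)
        matches = match_peaks(template, peaks, tr)
    return RunAlignment(matches=matches, transform=tr, inverse=inv)


def build_template(peak_sets: list[list[Peak2D]],
                   min_presence: int | None = None,
                   window: tuple[float, float] = DEFAULT_WINDOW,
                   dmf_min: int = DEFAULT_GATE, rmf_min: int = DEFAULT_GATE,
                   n_iter: int = 2) -> Template:
    """Build the reliable-peak template from all runs' detected peaks.

    The seed run is the medoid (maximum total matched DMF in a pilot
    all-vs-all pass).  The template is matched to every run, expected
    coordinates are updated to the mean of the matched (inverse-transformed)
    coordinates, and entries matched in at least ``min_presence`` runs
    (default: all but one) are retained.
    """
    n = len(peak_sets)
    if n < 2:
        raise ValueError("template building requires at least 2 runs")
    if min_presence is None:
        min_presence = n - 1

    def as_template(peaks: list[Peak2D]) -> Template:
        return Template(
            entries=[TemplateEntry(p.rt1, p.rt2, p.apex_spectrum) for p in peaks],
            window=window, dmf_min=dmf_min, rmf_min=rmf_min, n_source_runs=n,
        )

    # medoid: run whose peaks gather the highest total matched DMF
    totals = np.zeros(n)
    units = [_weighted_unit([p.apex_spectrum for p in ps]) for ps in peak_sets]
    for a in range(n):
        ta = as_template(peak_sets[a])
        ca = ta.coords()
        for b in range(n):
            if a == b or not peak_sets[b]:
                continue
            pk1 = np.array([p.rt1 for p in peak_sets[b]])
            pk2 = np.array([p.rt2 for p in peak_sets[b]])
            cos2 = np.clip(units[a] @ units[b].T, 0.0, 1.0) ** 2
            dmf_mat = np.floor(999.0 * cos2 + 0.5)
            ok = (np.abs(ca[:, 0:1] - pk1[None, :]) <= window[0]) & \
                 (np.abs(ca[:, 1:2] - pk2[None, :]) <= window[1]) & \
                 (dmf_mat >= dmf_min)
            if ok.any():
                totals[a] += np.where(ok, dmf_mat, 0).max(axis=1).sum()
    medoid = int(np.argmax(totals))

    template = as_template(peak_sets[medoid])
    alignments: list[RunAlignment] = []
    for _ in range(n_iter):
        alignments = [_fit_alignment(template, ps) for ps in peak_sets]
        # update expected coordinates to matched means in the template frame
        for i, entry in enumerate(template.entries):
            c1, c2, k = 0.0, 0.0, 0
            for al in alignments:
                p = al.matches.get(i)
                if p is None:
                    continue
                b1, b2 = al.inverse.apply(p.rt1, p.rt2)
                c1 += float(b1)
                c2 += float(b2)
                k += 1
            if k:
                entry.rt1, entry.rt2, entry.presence = c1 / k, c2 / k, k

    template.entries = [e for e in template.entries if e.presence >= min_presence]
    for new_id, e in enumerate(template.entries):
        e.entry_id = new_id
    return template


def align_runs(template: Template, peak_sets: list[list[Peak2D]]
               ) -> list[RunAlignment]:
    """Fit per-run transforms and final matches for a fixed template."""
    return [_fit_alignment(template, ps) for ps in peak_sets]


# ---------------------------------------------------------------------------
# Composite chromatogram and peak regions
# ---------------------------------------------------------------------------

def warp_raster(raster: np.ndarray, transform: RetentionTransform,
                p_m: float, acq_hz: float) -> np.ndarray:
    """Resample a run's TIC raster into the template frame."""
    n_mod, n_pts = raster.shape
    mods, pts = np.meshgrid(np.arange(n_mod), np.arange(n_pts), indexing="ij")
    rt1 = mods * p_m / 60.0
    rt2 = pts / acq_hz
    r1, r2 = transform.apply(rt1, rt2)
    coords = np.stack([r1 * 60.0 / p_m, r2 * acq_hz])
    return ndimage.map_coordinates(raster, coords, order=1, mode="nearest")


def build_composite(rasters: list[np.ndarray],
                    alignments: list[RunAlignment] | None = None,
                    p_m: float = 3.5, acq_hz: float = 100.0) -> np.ndarray:
    """Per-point mean of (optionally template-aligned) TIC rasters."""
    if not rasters:
        raise ValueError("composite requires at least one raster")
    if alignments is None:
        stack = np.stack([np.asarray(r, float) for r in rasters])
    else:
        stack = np.stack([
            warp_raster(np.asarray(r, float), al.transform, p_m, acq_hz)
            for r, al in zip(rasters, alignments)
        ])
    return stack.mean(axis=0)


@dataclass
class PeakRegion:
    """A delineated region of the composite chromatogram."""

    region_id: int
    apex_rt1: float
    apex_rt2: float
    points: np.ndarray          # (k, 2) raster indices
    template_covered: bool = False


def delineate_regions(composite: np.ndarray, template: Template,
                      p_m: float = 3.5, acq_hz: float = 100.0,
                      snr_min: float = 100.0) -> list[PeakRegion]:
    """Watershed peak-region delineation of the composite chromatogram.

    Regions whose footprint contains a template entry's apex are tagged
    ``template_covered``; the remainder are the untargeted peak-region
    features.
    """
    comp = np.asarray(composite, dtype=float)
    noise = estimate_noise(comp)
    baseline = float(np.median(comp))
    if noise == 0:
        return []
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed
    smoothed = ndimage.gaussian_filter(comp, sigma=(1.0, 3.0))
    sm_base = float(np.median(smoothed))
    sm_noise = estimate_noise(smoothed)
    coords = peak_local_max(smoothed, min_distance=2,
                            threshold_abs=sm_base + max(5.0 * sm_noise, 1e-12),
                            exclude_border=False)
    if coords.size == 0:
        return []
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
    markers = np.zeros(comp.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    mask = (smoothed > sm_base + 2.0 * sm_noise) | (markers > 0)
    labels = watershed(-smoothed, markers=markers, mask=mask)

    entry_idx = np.array([
        [int(round(e.rt1 * 60.0 / p_m)), int(round(e.rt2 * acq_hz))]
        for e in template.entries
    ]).reshape(-1, 2)

    regions: list[PeakRegion] = []
    rid = 0
    for i, (r, c) in enumerate(coords, start=1):
        region = labels == i
        apex_flat = np.argmax(np.where(region, comp, -np.inf))
        ar, ac = np.unravel_index(apex_flat, comp.shape)
        height = float(comp[ar, ac] - baseline)
        if height / noise < snr_min:
            continue
        floor = baseline + 0.05 * height
        foot = region & (comp >= floor)
        covered = any(
            0 <= er < comp.shape[0] and 0 <= ec < comp.shape[1] and foot[er, ec]
            for er, ec in entry_idx
        )
        regions.append(PeakRegion(
            region_id=rid, apex_rt1=ar * p_m / 60.0, apex_rt2=ac / acq_hz,
            points=np.argwhere(foot), template_covered=covered,
        ))
        rid += 1
    return regions


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

class MissingStandardError(ValueError):
    """A run matched neither internal standard."""


@dataclass
class FeatureTable:
    """UT features × samples response matrices with provenance metadata."""

    features: pd.DataFrame      # id, kind, identity, chem_class, rt1, rt2
    responses: pd.DataFrame     # features × samples, 2D peak volumes
    normalized: pd.DataFrame    # % normalized response over the ISs
    missing: pd.DataFrame       # bool, True where a response was imputed 0
    meta: list[SampleMeta] = field(default_factory=list)

    @property
    def n_targeted(self) -> int:
        return int((self.features["kind"] == "targeted").sum())

    @property
    def n_untargeted(self) -> int:
        return int((self.features["kind"] == "untargeted").sum())

    def class_of(self, sample_id: str) -> str:
        for m in self.meta:
            if m.sample_id == sample_id:
                return m.class_label
        raise KeyError(sample_id)

    def classes(self) -> pd.Series:
        return pd.Series({m.sample_id: m.class_label for m in self.meta}
                         )[self.responses.columns]


def save_feature_table(table: FeatureTable, outdir) -> None:
    """Persist a feature table as a directory of delimited-text files."""
    import pathlib
    d = pathlib.Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    table.features.to_csv(d / "features.csv", index=False)
    table.responses.to_csv(d / "responses.csv")
    table.normalized.to_csv(d / "normalized.csv")
    table.missing.to_csv(d / "missing.csv")
    pd.DataFrame([vars(m) for m in table.meta]).to_csv(d / "meta.csv", index=False)


def load_feature_table(outdir) -> FeatureTable:
    """Load a feature table written by :func:`save_feature_table`."""
    import pathlib
    d = pathlib.Path(outdir)
    features = pd.read_csv(d / "features.csv", keep_default_na=False)
    if not features.empty:
        features = features.set_index("feature_id", drop=False)
    responses = pd.read_csv(d / "responses.csv", index_col=0)
    normalized = pd.read_csv(d / "normalized.csv", index_col=0)
    missing = pd.read_csv(d / "missing.csv", index_col=0).astype(bool)
    meta = [SampleMeta(**row) for row in
            pd.read_csv(d / "meta.csv").to_dict(orient="records")]
    return FeatureTable(features=features, responses=responses,
                        normalized=normalized, missing=missing, meta=meta)


@dataclass
class ProcessedRun:
    """Detection output for one run: everything alignment needs."""

    meta: SampleMeta
    peaks: list[Peak2D]
    raster: np.ndarray
    p_m: float = 3.5
    acq_hz: float = 100.0

    @classmethod
    def from_chromatogram(cls, chrom: Chromatogram2D,
                          snr_min: float = 100.0) -> "ProcessedRun":
        return cls(meta=chrom.meta, peaks=detect_peaks(chrom, snr_min=snr_min),
                   raster=chrom.tic(), p_m=chrom.p_m, acq_hz=chrom.acq_hz)


def assemble_feature_table(
    template: Template,
    regions: list[PeakRegion],
    runs: list[ProcessedRun],
    alignments: list[RunAlignment] | None = None,
    internal_standards: list[tuple[str, float, float]] | None = None,
    library: list[TargetAnalyte] | None = None,
    cal: AlkaneCalibration | None = None,
    dmf_min: float = 900, rmf_min: float = 950, it_tol: float = 10.0,
) -> FeatureTable:
    """Assemble the UT feature table.

    One row per template entry (targeted when a library identity is assigned
    at the template coordinates; otherwise untargeted) and one per
    non-covered peak region.  Per-run responses are matched 2D peak volumes
    (template entries) or region-integrated volumes from the aligned raster
    (regions); unmatched cells are imputed 0 and flagged missing.  Rows for
    the internal standards are excluded and used as the normalisation
    denominator: %normalized = 100 × volume / mean(IS volumes in the run).
    """
    if alignments is None:
        alignments = align_runs(template, [r.peaks for r in runs])
    p_m = runs[0].p_m if runs else 3.5
    acq_hz = runs[0].acq_hz if runs else 100.0

    # locate IS entries among template entries by proximity
    is_entry_idx: dict[int, str] = {}
    if internal_standards:
        for name, rt1, rt2 in internal_standards:
            dists = [
                max(abs(e.rt1 - rt1) / template.window[0],
                    abs(e.rt2 - rt2) / template.window[1])
                for e in template.entries
            ]
            j = int(np.argmin(dists))
            if dists[j] <= 1.0:
                is_entry_idx[j] = name
            else:
                warnings.warn(f"internal standard {name!r} not found in template")

    # identities at template coordinates
    identities: dict[int, TargetAnalyte | None] = {}
    if library is not None and cal is not None:
        for i, e in enumerate(template.entries):
            if i in is_entry_idx:
                identities[i] = None
                continue
            pseudo = Peak2D(rt1=e.rt1, rt2=e.rt2, volume=1.0, height=1.0,
                            snr=np.inf, apex_spectrum=e.spectrum,
                            apex_index=(0, 0), footprint=np.empty((0, 2), int))
            identities[i] = assign_identity(pseudo, library, cal,
                                            dmf_min=dmf_min, rmf_min=rmf_min,
                                            it_tol=it_tol)
    else:
        identities = {i: None for i in range(len(template.entries))}

    sample_ids = [r.meta.sample_id for r in runs]
    feat_rows = []
    volumes = []
    missing = []

    entry_order = [i for i in range(len(template.entries)) if i not in is_entry_idx]
    for i in entry_order:
        e = template.entries[i]
        ident = identities.get(i)
        feat_rows.append({
            "feature_id": f"T{e.entry_id:03d}" if ident else f"U{e.entry_id:03d}",
            "kind": "targeted" if ident else "untargeted",
            "identity": ident.name if ident else "",
            "chem_class": ident.chem_class if ident else "",
            "rt1_min": e.rt1, "rt2_s": e.rt2,
            "origin": "peak",
        })
        row_v, row_m = [], []
        for al in alignments:
            p = al.matches.get(i)
            if p is None:
                row_v.append(0.0)
                row_m.append(True)
            else:
                row_v.append(p.volume)
                row_m.append(False)
        volumes.append(row_v)
        missing.append(row_m)

    open_regions = [r for r in regions if not r.template_covered]
    if open_regions:
        warped_runs = [
            warp_raster(run.raster, al.transform, p_m, acq_hz)
            for run, al in zip(runs, alignments)
        ]
        bases = [float(np.median(w)) for w in warped_runs]
        for reg in open_regions:
            feat_rows.append({
                "feature_id": f"R{reg.region_id:03d}",
                "kind": "untargeted", "identity": "", "chem_class": "",
                "rt1_min": reg.apex_rt1, "rt2_s": reg.apex_rt2,
                "origin": "region",
            })
            rr, cc = reg.points[:, 0], reg.points[:, 1]
            volumes.append([
                float(np.maximum(w[rr, cc] - b, 0.0).sum()) / 0.95
                for w, b in zip(warped_runs, bases)
            ])
            missing.append([False] * len(runs))

    features = pd.DataFrame(feat_rows)
    if features.empty:
        features = pd.DataFrame(columns=[
            "feature_id", "kind", "identity", "chem_class",
            "rt1_min", "rt2_s", "origin"])
    resp = pd.DataFrame(volumes, columns=sample_ids,
                        index=features.get("feature_id", pd.Index([])))
    miss = pd.DataFrame(missing, columns=sample_ids, index=resp.index)

    # internal-standard normalisation
    norm = resp.copy()
    if internal_standards:
        for col, al in zip(sample_ids, alignments):
            is_vols = [al.matches[j].volume for j in is_entry_idx
                       if al.matches.get(j) is not None]
            if not is_vols:
                raise MissingStandardError(
                    f"run {col!r} matched neither internal standard")
            norm[col] = 100.0 * resp[col] / float(np.mean(is_vols))
    features = features.set_index("feature_id", drop=False) if not features.empty \
        else features
    return FeatureTable(features=features, responses=resp, normalized=norm,
                        missing=miss, meta=[r.meta for r in runs])


def fingerprint_study(runs: list[ProcessedRun],
                      internal_standards: list[tuple[str, float, float]],
                      library: list[TargetAnalyte] | None = None,
                      cal: AlkaneCalibration | None = None,
                      min_presence: int | None = None,
                      snr_min: float = 100.0,
                      **identity_kwargs) -> tuple[FeatureTable, Template]:
    """End-to-end fingerprinting: template → composite → regions → table."""
    peak_sets = [r.peaks for r in runs]
    template = build_template(peak_sets, min_presence=min_presence)
    alignments = align_runs(template, peak_sets)
    composite = build_composite([r.raster for r in runs], alignments,
                                p_m=runs[0].p_m, acq_hz=runs[0].acq_hz)
    regions = delineate_regions(composite, template, p_m=runs[0].p_m,
                                acq_hz=runs[0].acq_hz, snr_min=snr_min)
    table = assemble_feature_table(
        template, regions, runs, alignments=alignments,
        internal_standards=internal_standards, library=library, cal=cal,
        **identity_kwargs)
    return table, template
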