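"""The targeted identification library (269 putatively identified volatiles).

The packaged fixture transcribes, verbatim, the printed table of target
components mapped across all silage runs: name, CAS registry number, chemical
class, mean retention coordinates with their %RSD, experimental and tabulated
linear retention indices, and the per-analyte Fisher ratio where reported.

Sentinel values are preserved as typed sentinels rather than coerced to
numbers: ``ND`` (a Fisher ratio that could not be computed because the feature
was invariant within a class), ``NC`` and ``>2500`` (retention indices outside
the calibrated alkane ladder).  Known internal inconsistencies of the printed
table (the prose says 269 targets and 37 aldehydes; the table prints 268 rows
with 36 aldehydes, and one CAS number is shared by two octadienone isomers)
are transcribed as-is and documented, not repaired.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

CHEM_CLASSES = (
    "alcohols", "aldehydes", "aromatics", "acids", "esters",
    "heterocyclic", "hydrocarbons", "ketones", "others", "terpenes",
)

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


class SentinelIndex:
    """Retention index outside the calibrated range ('NC' or '>2500')."""

    __slots__ = ("text",)

    def __init__(self, text: str):
        self.text = text

    def __repr__(self):
        return f"SentinelIndex({self.text!r})"

    def __eq__(self, other):
        return isinstance(other, SentinelIndex) and other.text == self.text

    def __hash__(self):
        return hash(("SentinelIndex", self.text))


#: Fisher ratio not determined (feature invariant within a class).
ND = math.nan


class LibraryError(ValueError):
    """Record-level validation failure while loading the target library."""


@dataclass(frozen=True)
class TargetAnalyte:
    """One row of the identification library."""

    name: str
    cas: str
    chem_class: str
    rt1_min: float          # first-dimension retention time, minutes
    rt1_rsd_pct: float      # %RSD of rt1 across the 35 runs
    rt2_s: float            # second-dimension retention time, seconds
    rt2_rsd_pct: float
    it_exp: float | SentinelIndex        # experimental linear retention index
    it_tab: float | None                 # tabulated (database) index, if any
    f_all: float                         # per-analyte Fisher ratio; NaN = ND

    def __post_init__(self):
        if not _CAS_RE.match(self.cas):
            raise LibraryError(f"malformed CAS number {self.cas!r} for {self.name!r}")
        if self.chem_class not in CHEM_CLASSES:
            raise LibraryError(f"unknown chemical class {self.chem_class!r}")
        if not self.rt1_min > 0:
            raise LibraryError(f"rt1_min must be positive ({self.name})")
        if not (0 <= self.rt2_s < 3.5):
            raise LibraryError(f"rt2_s must lie in [0, 3.5) ({self.name})")
        if self.rt1_rsd_pct < 0 or self.rt2_rsd_pct < 0:
            raise LibraryError(f"%RSD fields must be non-negative ({self.name})")

    @property
    def has_numeric_index(self) -> bool:
        return not isinstance(self.it_exp, SentinelIndex)

    @property
    def f_all_determined(self) -> bool:
        return not math.isnan(self.f_all)


def _parse_index(text: str) -> float | SentinelIndex:
    text = text.strip()
    if text in ("NC",) or text.startswith(">"):
        return SentinelIndex(text)
    return float(text)


def _parse_row(i: int, row: dict) -> TargetAnalyte:
    try:
        it_tab = row["it_tab"].strip()
        f_all = row["f_all"].strip()
        return TargetAnalyte(
            name=row["name"].strip(),
            cas=row["cas"].strip(),
            chem_class=row["class"].strip(),
            rt1_min=float(row["rt1_min"]),
            rt1_rsd_pct=float(row["rt1_rsd"]),
            rt2_s=float(row["rt2_s"]),
            rt2_rsd_pct=float(row["rt2_rsd"]),
            it_exp=_parse_index(row["it_exp"]),
            it_tab=float(it_tab) if it_tab else None,
            f_all=ND if f_all == "ND" else float(f_all),
        )
    except (KeyError, ValueError, LibraryError) as exc:
        raise LibraryError(f"row {i}: {exc}") from exc


def load_library(path=None) -> list[TargetAnalyte]:
    """Load a target library from delimited text (default: packaged fixture).

    The file is comma-separated UTF-8 with one header row and columns
    ``name, cas, class, rt1_min, rt1_rsd, rt2_s, rt2_rsd, it_exp, it_tab,
    f_all``.  Duplicate (CAS, name) pairs raise; a CAS shared by rows with
    different names (stereoisomer entries, as in the packaged table) only
    warns.
    """
    if path is None:
        ref = resources.files("gcxfp.data") / "target_library.csv"
        with ref.open("r", encoding="utf-8", newline="") as fh:
            return _load(fh)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _load(fh)


def _load(fh) -> list[TargetAnalyte]:
    reader = csv.DictReader(fh)
    analytes: list[TargetAnalyte] = []
    seen: dict[str, str] = {}
    for i, row in enumerate(reader, start=2):  # header is line 1
        rec = _parse_row(i, row)
        if rec.cas in seen:
            if seen[rec.cas] == rec.name:
                raise LibraryError(f"row {i}: duplicate CAS {rec.cas} ({rec.name})")
            warnings.warn(
                f"CAS {rec.cas} shared by {seen[rec.cas]!r} and {rec.name!r}",
                stacklevel=2,
            )
        seen.setdefault(rec.cas, rec.name)
        analytes.append(rec)
    return analytes


def write_library(analytes: Iterable[TargetAnalyte], path) -> None:
    """Write a library in the same delimited format (lossless round-trip)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "cas", "class", "rt1_min", "rt1_rsd", "rt2_s",
                    "rt2_rsd", "it_exp", "it_tab", "f_all"])
        for a in analytes:
            it_exp = a.it_exp.text if isinstance(a.it_exp, SentinelIndex) else repr(a.it_exp)
            w.writerow([
                a.name, a.cas, a.chem_class,
                repr(a.rt1_min), repr(a.rt1_rsd_pct),
                repr(a.rt2_s), repr(a.rt2_rsd_pct),
                it_exp,
                "" if a.it_tab is None else repr(a.it_tab),
                "ND" if math.isnan(a.f_all) else repr(a.f_all),
            ])


def class_counts(library: Iterable[TargetAnalyte]) -> dict[str, int]:
    """Number of analytes per chemical class (absent classes reported as 0)."""
    counts = {c: 0 for c in CHEM_CLASSES}
    for a in library:
        counts[a.chem_class] += 1
    return counts


def by_name(library: Iterable[TargetAnalyte], name: str) -> TargetAnalyte:
    for a in library:
        if a.name == name:
            return a
    raise KeyError(name)
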