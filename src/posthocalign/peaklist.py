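"""Peak-list containers, delimited-text I/O, and peak merging.

A GCxGC/TOF-MS deconvolution export (ChromaTOF-style) is one table per
technical replicate, one row per detected peak: compound name, CAS registry
number, first- and second-dimension retention times (seconds), peak area,
library-match similarity (0-999) and, optionally, the deconvoluted mass
spectrum.  Because a single compound frequently elutes as several nearby
peaks, downstream alignment works on *merged* lists in which each compound
identity is reduced to one representative peak (largest area or largest
library similarity).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

logger = logging.getLogger(__name__)

#: header names (lower-cased) recognised by the reader, in canonical order
REQUIRED_COLUMNS = ("name", "cas", "rt1", "rt2", "area", "similarity")
OPTIONAL_COLUMNS = ("spectrum",)

MERGE_RULES = ("area", "similarity")


class PeakListFormatError(ValueError):
    """The file does not look like a peak table (e.g. a column is missing)."""


class RowParseError(ValueError):
    """A data row could not be parsed (strict mode only); carries the line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Peak:
    """One detected chromatographic peak with its identification.

    ``spectrum`` maps integer m/z bins to non-negative intensities; bins not
    present are implicitly zero.
    """

    name: str
    cas: str
    rt1: float
    rt2: float
    area: float
    similarity: int
    spectrum: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not self.rt1 > 0:
            raise ValueError(f"rt1 must be > 0, got {self.rt1}")
        if not self.rt2 > 0:
            raise ValueError(f"rt2 must be > 0, got {self.rt2}")
        if not self.area > 0:
            raise ValueError(f"area must be > 0, got {self.area}")
        if not 0 <= self.similarity <= 999:
            raise ValueError(f"similarity must be in [0, 999], got {self.similarity}")
        if self.spectrum is not None:
            if not self.spectrum:
                raise ValueError("spectrum, when present, must be non-empty")
            if any(v < 0 for v in self.spectrum.values()):
                raise ValueError("spectrum intensities must be non-negative")
            if not any(v > 0 for v in self.spectrum.values()):
                raise ValueError("spectrum must have at least one positive intensity")

    @property
    def key(self) -> str:
        """Grouping key for merging and name-based alignment.

        CAS number when non-empty, otherwise the lower-cased compound name
        (names from real exports carry formatting noise; CAS does not).
        """
        cas = self.cas.strip()
        return cas if cas else self.name.strip().lower()


@dataclass
class PeakList:
    """All peaks of one experiment replicate, pre- or post-merging."""

    replicate_id: str
    peaks: list[Peak] = field(default_factory=list)
    merged: bool = False

    def __post_init__(self) -> None:
        if self.merged:
            keys = [p.key for p in self.peaks]
            if len(set(keys)) != len(keys):
                raise ValueError(
                    f"PeakList {self.replicate_id!r} flagged merged but grouping "
                    "keys are not unique"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def keys(self) -> list[str]:
        return [p.key for p in self.peaks]


def format_spectrum(spectrum: dict[int, float]) -> str:
    """Serialise a spectrum as space-separated ``mz:intensity`` tokens."""
    return " ".join(f"{mz}:{val!r}" for mz, val in sorted(spectrum.items()))


def parse_spectrum(text: str) -> dict[int, float] | None:
    text = text.strip()
    if not text:
        return None
    spectrum: dict[int, float] = {}
    for token in text.split():
        mz_s, _, val_s = token.partition(":")
        spectrum[int(mz_s)] = float(val_s)
    return spectrum


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_peaklist(
    path: str | Path,
    *,
    replicate_id: str | None = None,
    strict: bool = False,
    delimiter: str | None = None,
    merged: bool = False,
) -> PeakList:
    """Read a delimited peak table into a :class:`PeakList`.

    The header must contain (case-insensitively) Name, CAS, RT1, RT2, Area
    and Similarity; a Spectrum column is optional.  The delimiter is
    auto-detected between comma and tab unless given.  In lenient mode
    (default) rows violating the :class:`Peak` invariants or failing numeric
    parsing are skipped with a logged count; in strict mode the first bad row
    raises :class:`RowParseError` with its line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise PeakListFormatError(f"{path}: empty file (no header)")
        delim = delimiter or _detect_delimiter(first)
        header = [c.strip().lower() for c in next(csv.reader([first], delimiter=delim))]
        colmap = {name: i for i, name in enumerate(header)}
        for col in REQUIRED_COLUMNS:
            if col not in colmap:
                raise PeakListFormatError(f"{path}: missing mandatory column {col!r}")
        has_spectrum = "spectrum" in colmap

        peaks: list[Peak] = []
        skipped = 0
        reader = csv.reader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                cell = lambda col: row[colmap[col]].strip()  # noqa: E731
                peak = Peak(
                    name=cell("name"),
                    cas=cell("cas"),
                    rt1=float(cell("rt1")),
                    rt2=float(cell("rt2")),
                    area=float(cell("area")),
                    similarity=int(float(cell("similarity"))),
                    spectrum=parse_spectrum(cell("spectrum")) if has_spectrum else None,
                )
            except (ValueError, IndexError) as exc:
                if strict:
                    raise RowParseError(lineno, str(exc)) from exc
                skipped += 1
                continue
            peaks.append(peak)

    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    rid = replicate_id if replicate_id is not None else path.stem
    return PeakList(replicate_id=rid, peaks=peaks, merged=merged)


def write_peaklist(plist: PeakList, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a :class:`PeakList` so that :func:`read_peaklist` recovers it exactly.

    Floats are written with ``repr`` (round-trip exact); the Spectrum column
    is emitted only when at least one peak carries a spectrum.
    """
    path = Path(path)
    has_spectrum = any(p.spectrum is not None for p in plist.peaks)
    header = ["Name", "CAS", "RT1", "RT2", "Area", "Similarity"]
    if has_spectrum:
        header.append("Spectrum")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for p in plist.peaks:
            row = [p.name, p.cas, repr(p.rt1), repr(p.rt2), repr(p.area), str(p.similarity)]
            if has_spectrum:
                row.append(format_spectrum(p.spectrum) if p.spectrum is not None else "")
            writer.writerow(row)


def merge_peaks(plist: PeakList, rule: str) -> PeakList:
    """Reduce multiple peaks per compound to one representative peak.

    Peaks sharing a grouping key (CAS, else lower-cased name) are collapsed
    to the group member with the largest area (``rule="area"``) or the
    largest library similarity (``rule="similarity"``).  Either rule yields
    the same number of peaks — one per distinct key — it only changes which
    member represents the group.  Ties on the maximal value are broken by
    smallest rt1, then smallest rt2, for deterministic output.  The
    representative is always an input peak; no fields are synthesised.
    """
    if rule not in MERGE_RULES:
        raise ValueError(f"unknown merge rule {rule!r}; expected one of {MERGE_RULES}")
    if plist.merged:
        raise ValueError(f"PeakList {plist.replicate_id!r} is already merged")

    groups: dict[str, list[Peak]] = {}
    for peak in plist.peaks:
        groups.setdefault(peak.key, []).append(peak)

    attr = "area" if rule == "area" else "similarity"
    representatives = [
        min(group, key=lambda p: (-getattr(p, attr), p.rt1, p.rt2))
        for group in groups.values()
    ]
    return PeakList(replicate_id=plist.replicate_id, peaks=representatives, merged=True)


def distinct_key_count(plist: PeakList) -> int:
    """Number of distinct grouping keys, i.e. the post-merging peak count."""
    return len(set(plist.keys))
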