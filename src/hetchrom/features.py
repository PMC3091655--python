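"""Repeat classification, genome windows, and per-window feature tabulation.

Eight molecular features are tracked per genomic window: protein-coding
genes, DNA transposable elements, RNA transposable elements (retroelements),
segmental duplications (SDs), micro-/mini-/satellites, and matrix attachment
regions (MARs).

Tandem repeats are accepted only with >= 80% matches and a copy number of 2
or more (8 or more for microsatellites), and binned by repeat-unit period:
2-6 bp microsatellite, 7-99 bp minisatellite, >= 100 bp satellite. Putative
SDs are kept only for pairwise alignments >= 2.5 kb long with > 90% sequence
identity. Genes and MARs carry no thresholds and pass through unchanged.

Windows tile each chromatin region exactly: 5-Mb intervals in euchromatin
and sub-1-Mb intervals in heterochromatin, split near-equally so that no
window crosses a region (and hence a chromatin-class) boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import ChromatinRegion, EUCHROMATIN_CLASSES

__all__ = [
    "FEATURE_CLASSES",
    "FeatureInterval",
    "GenomicWindow",
    "WindowFeatureRecord",
    "classify_tandem_repeat",
    "filter_segmental_duplication",
    "make_windows",
    "tabulate",
    "records_to_frame",
    "frame_to_records",
    "summarize_by_class",
    "landscape",
    "read_repeatmasker_out",
    "read_trf_dat",
    "read_bed_features",
    "read_unified_features",
]

logger = logging.getLogger(__name__)

FEATURE_CLASSES = (
    "gene",
    "dna_te",
    "rna_te",
    "sd",
    "microsatellite",
    "minisatellite",
    "satellite",
    "mar",
)

TANDEM_CLASSES = ("microsatellite", "minisatellite", "satellite")


@dataclass(frozen=True)
class FeatureInterval:
    """A classified feature interval (1-based start, exclusive end)."""

    arm: str
    start: int
    end: int
    feature_class: str
    period: int | None = None
    copy_number: float | None = None
    percent_match: float | None = None
    aligned_length: int | None = None
    percent_identity: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicWindow:
    """An analysis window within a single chromatin region."""

    arm: str
    start: int
    end: int
    chromatin_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowFeatureRecord:
    """Count C and union bp coverage K of one feature in one window."""

    window: GenomicWindow
    feature_class: str
    count: int
    coverage: int

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= self.window.length:
            raise ValueError("coverage must lie in [0, window length]")
        if self.count < 0:
            raise ValueError("count must be nonnegative")


def classify_tandem_repeat(
    period: int, copy_number: float, percent_match: float
) -> str:
    """Classify one tandem-repeat record, or reject it.

    Returns one of ``microsatellite`` (period 2-6), ``minisatellite``
    (7-99), ``satellite`` (>= 100) or ``rejected``. Acceptance needs
    percent_match >= 80 and copy_number >= 2, tightened to >= 8 copies for
    microsatellite periods; period-1 homopolymer runs are always rejected.
    """
    if period < 2:
        return "rejected"
    if percent_match < 80:
        return "rejected"
    min_copies = 8 if period <= 6 else 2
    if copy_number < min_copies:
        return "rejected"
    if period <= 6:
        return "microsatellite"
    if period <= 99:
        return "minisatellite"
    return "satellite"


def filter_segmental_duplication(
    aligned_length: float, percent_identity: float
) -> bool:
    """Keep a putative SD alignment iff >= 2,500 bp and identity > 90 (strict)."""
    return aligned_length >= 2500 and percent_identity > 90


def make_windows(
    regions: Sequence[ChromatinRegion],
    eu_window: int = 5_000_000,
    het_window: int = 1_000_000,
) -> list[GenomicWindow]:
    """Tile each region with near-equal windows.

    Euchromatic regions (EU, PEU) are split into ``ceil(size / eu_window)``
    windows, heterochromatic ones (PH, IHc, IHd) into
    ``ceil(size / het_window)``; the ceiling division makes heterochromatin
    windows strictly shorter than ``het_window`` whenever the region size is
    not an exact multiple. Window lengths within a region differ by at most
    1 bp and sum exactly to the region size.
    """
    if eu_window <= 0 or het_window <= 0:
        raise ValueError("window sizes must be positive")
    windows: list[GenomicWindow] = []
    for region in regions:
        target = eu_window if region.chromatin_class in EUCHROMATIN_CLASSES else het_window
        n = max(1, math.ceil(region.size / target))
        base, extra = divmod(region.size, n)
        pos = region.start
        for i in range(n):
            length = base + (1 if i < extra else 0)
            windows.append(
                GenomicWindow(
                    arm=region.arm,
                    start=pos,
                    end=pos + length,
                    chromatin_class=region.chromatin_class,
                )
            )
            pos += length
        assert pos == region.end
    return windows


def _merge_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for s, e in spans[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def tabulate(
    windows: Sequence[GenomicWindow],
    intervals: Iterable[FeatureInterval],
    feature_classes: Sequence[str] = FEATURE_CLASSES,
) -> list[WindowFeatureRecord]:
    """Per-window count C and union coverage K for each feature class.

    An interval is *counted* in the window containing its start position, so
    each interval contributes exactly one count genome-wide; its *coverage*
    is clipped to every window it overlaps, with same-class intervals merged
    before measuring so overlapping copies are not double-counted. Intervals
    on arms absent from the window set are skipped with a warning.
    """
    win_by_arm: dict[str, list[GenomicWindow]] = {}
    for w in sorted(windows, key=lambda w: (w.arm, w.start)):
        win_by_arm.setdefault(w.arm, []).append(w)

    ivs_by_key: dict[tuple[str, str], list[FeatureInterval]] = {}
    skipped = 0
    for iv in intervals:
        if iv.arm not in win_by_arm:
            skipped += 1
            logger.warning(
                "interval %s:[%d,%d) (%s) on arm without windows; skipped",
                iv.arm, iv.start, iv.end, iv.feature_class,
            )
            continue
        ivs_by_key.setdefault((iv.arm, iv.feature_class), []).append(iv)
    if skipped:
        logger.warning("%d intervals skipped (arm not in window set)", skipped)

    records: list[WindowFeatureRecord] = []
    for arm, wins in win_by_arm.items():
        starts = np.array([w.start for w in wins])
        ends = np.array([w.end for w in wins])
        for fclass in feature_classes:
            ivs = ivs_by_key.get((arm, fclass), [])
            counts = np.zeros(len(wins), dtype=int)
            if ivs:
                iv_starts = np.array([iv.start for iv in ivs])
                # window containing the start: last window with start <= s,
                # provided s < its end (starts in inter-region gaps drop out)
                idx = np.searchsorted(starts, iv_starts, side="right") - 1
                ok = (idx >= 0) & (iv_starts < ends[np.clip(idx, 0, None)])
                np.add.at(counts, idx[ok], 1)
            merged = _merge_intervals([(iv.start, iv.end) for iv in ivs])
            mstarts = np.array([s for s, _ in merged])
            mends = np.array([e for _, e in merged])
            for wi, w in enumerate(wins):
                if merged:
                    clip_s = np.maximum(mstarts, w.start)
                    clip_e = np.minimum(mends, w.end)
                    cov = int(np.maximum(clip_e - clip_s, 0).sum())
                else:
                    cov = 0
                records.append(
                    WindowFeatureRecord(
                        window=w,
                        feature_class=fclass,
                        count=int(counts[wi]),
                        coverage=cov,
                    )
                )
    return records


def records_to_frame(records: Sequence[WindowFeatureRecord]) -> pd.DataFrame:
    """Flatten records to the window feature table (TSV-ready)."""
    return pd.DataFrame(
        {
            "arm": [r.window.arm for r in records],
            "window_start": [r.window.start for r in records],
            "window_end": [r.window.end for r in records],
            "class": [r.window.chromatin_class for r in records],
            "feature": [r.feature_class for r in records],
            "C": [r.count for r in records],
            "K": [r.coverage for r in records],
            "L": [r.window.length for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[WindowFeatureRecord]:
    """Inverse of :func:`records_to_frame`."""
    return [
        WindowFeatureRecord(
            window=GenomicWindow(
                arm=row.arm,
                start=int(row.window_start),
                end=int(row.window_end),
                chromatin_class=row["class"],
            ),
            feature_class=row.feature,
            count=int(row.C),
            coverage=int(row.K),
        )
        for _, row in df.iterrows()
    ]


def summarize_by_class(records: Sequence[WindowFeatureRecord]) -> pd.DataFrame:
    """Median per-window density and coverage fraction per chromatin class.

    Density is count per Mb of window; coverage fraction is the percent of
    window bp covered. Classes with zero windows are omitted with a warning.
    """
    df = records_to_frame(records)
    if df.empty:
        logger.warning("no records to summarize")
        return pd.DataFrame(
            columns=["class", "feature", "median_density_per_mb", "median_coverage_pct"]
        )
    df["density_per_mb"] = df["C"] / (df["L"] / 1e6)
    df["coverage_pct"] = 100.0 * df["K"] / df["L"]
    out = (
        df.groupby(["class", "feature"], sort=False)[["density_per_mb", "coverage_pct"]]
        .median()
        .reset_index()
        .rename(
            columns={
                "density_per_mb": "median_density_per_mb",
                "coverage_pct": "median_coverage_pct",
            }
        )
    )
    return out


def landscape(records: Sequence[WindowFeatureRecord]) -> pd.DataFrame:
    """Arm-ordered landscape rows (window midpoint vs density/coverage)."""
    df = records_to_frame(records)
    df["midpoint"] = (df["window_start"] + df["window_end"]) / 2.0
    df["density_per_mb"] = df["C"] / (df["L"] / 1e6)
    df["coverage_pct"] = 100.0 * df["K"] / df["L"]
    return df.sort_values(["arm", "midpoint", "feature"]).reset_index(drop=True)[
        ["arm", "midpoint", "class", "feature", "density_per_mb", "coverage_pct"]
    ]


# ---------------------------------------------------------------------------
# input parsers

#: RepeatMasker class/family prefixes mapped onto the two TE feature classes.
_RM_CLASS_MAP = (
    ("DNA", "dna_te"),
    ("RC", "dna_te"),  # rolling-circle (Helitron) elements transpose via DNA
    ("LINE", "rna_te"),
    ("SINE", "rna_te"),
    ("LTR", "rna_te"),
    ("Retro", "rna_te"),
)


def _te_class(family: str) -> str | None:
    for prefix, cls in _RM_CLASS_MAP:
        if family.startswith(prefix):
            return cls
    return None


def read_repeatmasker_out(path: str | Path) -> list[FeatureInterval]:
    """Parse a RepeatMasker ``.out``-style table into TE intervals.

    Uses the query name, begin/end (1-based inclusive, converted to the
    exclusive-end convention) and the repeat class/family column; families
    outside the DNA/retroelement groups (simple repeats, low complexity,
    rRNA, unknowns) are skipped.
    """
    intervals: list[FeatureInterval] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 11 or not parts[0].replace(".", "").isdigit():
            continue  # header/blank lines
        query, qbegin, qend = parts[4], int(parts[5]), int(parts[6])
        family = parts[10]
        cls = _te_class(family)
        if cls is None:
            continue
        intervals.append(
            FeatureInterval(arm=query, start=qbegin, end=qend + 1, feature_class=cls)
        )
    return intervals


def read_trf_dat(path: str | Path) -> list[FeatureInterval]:
    """Parse Tandem Repeats Finder ``.dat``-style output, applying the
    acceptance thresholds and period binning of :func:`classify_tandem_repeat`.

    Data lines carry ``start end period copies consensus_size pct_match ...``
    (1-based inclusive coordinates); ``Sequence:`` headers set the arm.
    Rejected records are dropped.
    """
    intervals: list[FeatureInterval] = []
    arm: str | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("Sequence:"):
            arm = line.split(None, 1)[1].split()[0]
            continue
        parts = line.split()
        if len(parts) < 6 or not parts[0].isdigit():
            continue
        if arm is None:
            raise ValueError("TRF data line before any 'Sequence:' header")
        start, end = int(parts[0]), int(parts[1])
        period = int(parts[2])
        copies = float(parts[3])
        pct_match = float(parts[5])
        cls = classify_tandem_repeat(period, copies, pct_match)
        if cls == "rejected":
            continue
        intervals.append(
            FeatureInterval(
                arm=arm,
                start=start,
                end=end + 1,
                feature_class=cls,
                period=period,
                copy_number=copies,
                percent_match=pct_match,
            )
        )
    return intervals


def read_bed_features(path: str | Path, feature_class: str) -> list[FeatureInterval]:
    """Read gene/MAR/SD intervals from BED-like TSV (0-based half-open).

    SD rows may carry ``aligned_length`` and ``percent_identity`` in columns
    5 and 6 (after name); rows failing the SD filter are dropped.
    """
    intervals: list[FeatureInterval] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split("\t")
        arm, bstart, bend = parts[0], int(parts[1]), int(parts[2])
        start, end = bstart + 1, bend + 1
        if feature_class == "sd" and len(parts) >= 6:
            alen, ident = float(parts[4]), float(parts[5])
            if not filter_segmental_duplication(alen, ident):
                continue
            intervals.append(
                FeatureInterval(
                    arm=arm, start=start, end=end, feature_class="sd",
                    aligned_length=int(alen), percent_identity=ident,
                )
            )
        else:
            intervals.append(
                FeatureInterval(arm=arm, start=start, end=end, feature_class=feature_class)
            )
    return intervals


def read_unified_features(path: str | Path) -> list[FeatureInterval]:
    """Read the unified feature TSV, applying all stated filters.

    Columns: ``arm start end feature_class period copies match identity
    length`` (1-based start, exclusive end; empty/``.`` for inapplicable
    attributes). Tandem-repeat rows are (re)classified from their
    attributes; SD rows are filtered; records failing a filter are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[FeatureInterval] = []

    def _num(v: str) -> float | None:
        v = v.strip()
        return None if v in ("", ".") else float(v)

    for _, row in df.iterrows():
        fclass = row["feature_class"]
        start, end = int(row["start"]), int(row["end"])
        period = _num(row.get("period", ""))
        copies = _num(row.get("copies", ""))
        match = _num(row.get("match", ""))
        identity = _num(row.get("identity", ""))
        length = _num(row.get("length", ""))
        if fclass in TANDEM_CLASSES or fclass == "tandem":
            if period is None or copies is None or match is None:
                raise ValueError(f"tandem repeat row lacks attributes: {row.to_dict()}")
            cls = classify_tandem_repeat(int(period), copies, match)
            if cls == "rejected":
                continue
            out.append(
                FeatureInterval(
                    arm=row["arm"], start=start, end=end, feature_class=cls,
                    period=int(period), copy_number=copies, percent_match=match,
                )
            )
        elif fclass == "sd":
            alen = length if length is not None else end - start
            if identity is None or not filter_segmental_duplication(alen, identity):
                continue
            out.append(
                FeatureInterval(
                    arm=row["arm"], start=start, end=end, feature_class="sd",
                    aligned_length=int(alen), percent_identity=identity,
                )
            )
        elif fclass in FEATURE_CLASSES:
            out.append(
                FeatureInterval(arm=row["arm"], start=start, end=end, feature_class=fclass)
            )
        else:
            raise ValueError(f"unknown feature_class {fclass!r}")
    return out
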