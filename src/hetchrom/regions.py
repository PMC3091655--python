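"""Chromatin-region maps: parsing, validation, and boundary statistics.

The unit of analysis is a cytologically mapped chromatin region on one of the
five *Anopheles gambiae* chromosome arms (X, 2R, 2L, 3R, 3L), carrying one of
five chromatin classes:

====  ====================================
EU    (distal) euchromatin
PEU   proximal euchromatin
PH    pericentric heterochromatin
IHc   compact intercalary heterochromatin
IHd   diffuse intercalary heterochromatin
====  ====================================

Coordinates are 1-based starts with exclusive ends, so a region's size is
``end - start`` — the only convention consistent with the published boundary
table, where every printed size equals the end coordinate minus the start
coordinate. Adjacent regions on an arm never overlap; the gap between the
outermost euchromatic and heterochromatic markers of consecutive regions is a
*transition zone*.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ARMS",
    "CHROMATIN_CLASSES",
    "HETEROCHROMATIN_CLASSES",
    "EUCHROMATIN_CLASSES",
    "ChromatinRegion",
    "TransitionZone",
    "ChromatinSummary",
    "RegionValidationError",
    "read_region_table",
    "region_size",
    "transition_zones",
    "summarize_chromatin",
    "write_bed",
    "read_bed",
    "load_agamp3_regions",
    "agamp3_region_path",
]

ARMS = ("X", "2R", "2L", "3R", "3L")
#: Label set A of the count model, in its canonical order.
CHROMATIN_CLASSES = ("EU", "PH", "IHc", "PEU", "IHd")
HETEROCHROMATIN_CLASSES = frozenset({"PH", "IHc", "IHd"})
EUCHROMATIN_CLASSES = frozenset({"EU", "PEU"})

#: Default refinement of an undifferentiated "IH" label by arm: the 3R block
#: is the compact type, the 2L and 3L blocks the diffuse type.
_IH_DEFAULT_SUBCLASS = {"3R": "IHc", "2L": "IHd", "3L": "IHd"}


class RegionValidationError(ValueError):
    """A region table row violates the chromatin-map invariants."""


@dataclass(frozen=True)
class ChromatinRegion:
    """A labelled genomic interval of one chromatin class.

    ``start`` is 1-based; ``end`` is exclusive; ``size == end - start``.
    """

    arm: str
    chromatin_class: str
    start: int
    end: int
    gene_count: int | None = None
    start_marker: str | None = None
    end_marker: str | None = None

    def __post_init__(self) -> None:
        if self.chromatin_class not in CHROMATIN_CLASSES:
            raise RegionValidationError(
                f"unknown chromatin class {self.chromatin_class!r} "
                f"(expected one of {CHROMATIN_CLASSES})"
            )
        if self.start < 1:
            raise RegionValidationError(f"start must be >= 1, got {self.start}")
        if self.end <= self.start:
            raise RegionValidationError(
                f"end ({self.end}) must exceed start ({self.start})"
            )
        if self.gene_count is not None and self.gene_count < 0:
            raise RegionValidationError("gene_count must be nonnegative")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def is_heterochromatin(self) -> bool:
        return self.chromatin_class in HETEROCHROMATIN_CLASSES


@dataclass(frozen=True)
class TransitionZone:
    """The gap between two adjacent mapped regions on an arm."""

    arm: str
    left_class: str
    right_class: str
    start: int  # left region's end
    end: int  # right region's start

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class ChromatinSummary:
    """Aggregate bp and gene-count statistics of a chromatin map."""

    bp_by_class: dict[str, int]
    genes_by_class: dict[str, int | None]
    heterochromatin_bp: int
    euchromatin_bp: int
    total_bp: int
    heterochromatin_genes: int | None
    euchromatin_genes: int | None
    total_genes_mapped: int | None
    genome_size: int
    total_genes: int
    genome_fraction: float = field(init=False)
    gene_fraction: float | None = field(init=False)
    gene_density_by_class: dict[str, float | None] = field(init=False)

    def __post_init__(self) -> None:
        self.genome_fraction = 100.0 * self.heterochromatin_bp / self.genome_size
        self.gene_fraction = (
            100.0 * self.heterochromatin_genes / self.total_genes
            if self.heterochromatin_genes is not None
            else None
        )
        self.gene_density_by_class = {
            cls: (
                self.genes_by_class[cls] / (self.bp_by_class[cls] / 1e6)
                if self.genes_by_class.get(cls) is not None
                and self.bp_by_class.get(cls, 0) > 0
                else None
            )
            for cls in self.bp_by_class
        }

    def to_dict(self) -> dict:
        return {
            "bp_by_class": self.bp_by_class,
            "genes_by_class": self.genes_by_class,
            "heterochromatin_bp": self.heterochromatin_bp,
            "euchromatin_bp": self.euchromatin_bp,
            "total_bp": self.total_bp,
            "heterochromatin_genes": self.heterochromatin_genes,
            "euchromatin_genes": self.euchromatin_genes,
            "total_genes_mapped": self.total_genes_mapped,
            "genome_size": self.genome_size,
            "total_genes": self.total_genes,
            "genome_fraction_pct": round(self.genome_fraction, 1),
            "gene_fraction_pct": (
                round(self.gene_fraction, 1) if self.gene_fraction is not None else None
            ),
            "gene_density_per_mb_by_class": {
                k: (round(v, 2) if v is not None else None)
                for k, v in self.gene_density_by_class.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _refine_class(raw: str, subclass: str | None, arm: str, row: int) -> str:
    raw = raw.strip()
    if raw in ("EU", "PEU", "PH", "IHc", "IHd"):
        return raw
    if raw == "CH":
        return "PH"
    if raw == "IH":
        if subclass in ("c", "d"):
            return "IH" + subclass
        if subclass in ("IHc", "IHd"):
            return subclass
        refined = _IH_DEFAULT_SUBCLASS.get(arm)
        if refined is None:
            raise RegionValidationError(
                f"row {row}: IH region on arm {arm!r} needs an explicit subclass"
            )
        return refined
    raise RegionValidationError(f"row {row}: unknown chromatin class {raw!r}")


def _sort_and_check(regions: Iterable[ChromatinRegion]) -> list[ChromatinRegion]:
    """Sort per arm (arms in canonical order) and enforce non-overlap."""
    by_arm: dict[str, list[ChromatinRegion]] = {}
    for r in regions:
        by_arm.setdefault(r.arm, []).append(r)
    out: list[ChromatinRegion] = []
    arm_order = {a: i for i, a in enumerate(ARMS)}
    for arm in sorted(by_arm, key=lambda a: arm_order.get(a, len(ARMS))):
        rs = sorted(by_arm[arm], key=lambda r: r.start)
        for prev, nxt in zip(rs, rs[1:]):
            if nxt.start < prev.end:
                raise RegionValidationError(
                    f"regions overlap on arm {arm}: "
                    f"[{prev.start}, {prev.end}) and [{nxt.start}, {nxt.end})"
                )
        out.extend(rs)
    return out


def read_region_table(path: str | Path) -> list[ChromatinRegion]:
    """Read a chromatin-region TSV into validated, per-arm-sorted regions.

    Expected columns: ``arm  class  start  end`` with optional ``gene_count``,
    ``start_marker``, ``end_marker`` and ``subclass``. ``class`` may be the
    published coarse label (``CH`` for pericentric, ``IH`` for intercalary
    heterochromatin) or an already refined one; ``subclass`` (``c``/``d``)
    refines ``IH`` rows, defaulting to compact on 3R and diffuse on 2L/3L.

    Raises :class:`RegionValidationError` naming the offending 1-based data
    row on any invariant violation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"arm", "class", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise RegionValidationError(f"missing required columns: {sorted(missing)}")

    regions: list[ChromatinRegion] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        arm = row["arm"].strip()
        subclass = row.get("subclass", "") or None
        if subclass is not None:
            subclass = subclass.strip() or None
        cls = _refine_class(row["class"], subclass, arm, rownum)
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise RegionValidationError(f"row {rownum}: bad coordinate: {exc}") from exc
        gene_raw = str(row.get("gene_count", "")).strip()
        gene_count = int(gene_raw) if gene_raw not in ("", ".") else None
        try:
            region = ChromatinRegion(
                arm=arm,
                chromatin_class=cls,
                start=start,
                end=end,
                gene_count=gene_count,
                start_marker=(row.get("start_marker") or None),
                end_marker=(row.get("end_marker") or None),
            )
        except RegionValidationError as exc:
            raise RegionValidationError(f"row {rownum}: {exc}") from exc
        regions.append(region)

    # overlap check that names the offending data row
    rownums = {id(r): i + 1 for i, r in enumerate(regions)}
    by_arm: dict[str, list[ChromatinRegion]] = {}
    for r in regions:
        by_arm.setdefault(r.arm, []).append(r)
    for arm, rs in by_arm.items():
        rs = sorted(rs, key=lambda r: r.start)
        for prev, nxt in zip(rs, rs[1:]):
            if nxt.start < prev.end:
                raise RegionValidationError(
                    f"row {rownums[id(nxt)]}: region [{nxt.start}, {nxt.end}) on arm "
                    f"{arm} overlaps [{prev.start}, {prev.end})"
                )
    return _sort_and_check(regions)


def region_size(region: ChromatinRegion) -> int:
    """Size in bp, ``end - start`` (matches the published size column)."""
    return region.size


def transition_zones(regions: Sequence[ChromatinRegion]) -> list[TransitionZone]:
    """One zone per adjacent region pair on each arm.

    The zone spans from the left region's end to the right region's start —
    the stretch between the outermost mapped markers of the two flanking
    regions. Zero-size zones (abutting regions) are retained.
    """
    zones: list[TransitionZone] = []
    by_arm: dict[str, list[ChromatinRegion]] = {}
    for r in _sort_and_check(regions):
        by_arm.setdefault(r.arm, []).append(r)
    arm_order = {a: i for i, a in enumerate(ARMS)}
    for arm in sorted(by_arm, key=lambda a: arm_order.get(a, len(ARMS))):
        rs = by_arm[arm]
        for left, right in zip(rs, rs[1:]):
            zones.append(
                TransitionZone(
                    arm=arm,
                    left_class=left.chromatin_class,
                    right_class=right.chromatin_class,
                    start=left.end,
                    end=right.start,
                )
            )
    return zones


def zone_stats_kb(zones: Sequence[TransitionZone]) -> dict[str, int]:
    """Mean/min/max transition-zone size rounded to the nearest kb."""
    if not zones:
        return {"n": 0, "mean_kb": 0, "min_kb": 0, "max_kb": 0}
    sizes = [z.size for z in zones]
    return {
        "n": len(zones),
        "mean_kb": round(sum(sizes) / len(sizes) / 1000),
        "min_kb": round(min(sizes) / 1000),
        "max_kb": round(max(sizes) / 1000),
    }


def summarize_chromatin(
    regions: Sequence[ChromatinRegion],
    genome_size: int = 260_000_000,
    total_genes: int = 13_000,
) -> ChromatinSummary:
    """Aggregate bp and gene counts per chromatin class.

    Heterochromatin totals sum the PH, IHc and IHd classes; euchromatin the
    EU and PEU classes. Fractions are taken against ``genome_size`` and
    ``total_genes``. If any region of a compartment lacks a gene count, that
    compartment's gene total is reported as absent (None), never as zero.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    bp: dict[str, int] = {}
    genes: dict[str, int | None] = {}
    for r in regions:
        bp[r.chromatin_class] = bp.get(r.chromatin_class, 0) + r.size
        if r.chromatin_class not in genes:
            genes[r.chromatin_class] = 0
        if genes[r.chromatin_class] is None or r.gene_count is None:
            genes[r.chromatin_class] = None
        else:
            genes[r.chromatin_class] += r.gene_count  # type: ignore[operator]

    def _total(classes: frozenset[str], table: dict) -> int | None:
        vals = [table[c] for c in table if c in classes]
        if any(v is None for v in vals):
            return None
        return sum(vals)

    het_bp = sum(v for c, v in bp.items() if c in HETEROCHROMATIN_CLASSES)
    eu_bp = sum(v for c, v in bp.items() if c in EUCHROMATIN_CLASSES)
    het_genes = _total(HETEROCHROMATIN_CLASSES, genes)
    eu_genes = _total(EUCHROMATIN_CLASSES, genes)
    total_mapped = (
        het_genes + eu_genes
        if het_genes is not None and eu_genes is not None
        else None
    )
    return ChromatinSummary(
        bp_by_class=bp,
        genes_by_class=genes,
        heterochromatin_bp=het_bp,
        euchromatin_bp=eu_bp,
        total_bp=het_bp + eu_bp,
        heterochromatin_genes=het_genes,
        euchromatin_genes=eu_genes,
        total_genes_mapped=total_mapped,
        genome_size=genome_size,
        total_genes=total_genes,
    )


def write_bed(
    items: Sequence[ChromatinRegion] | Sequence[TransitionZone], path: str | Path
) -> None:
    """Write regions or transition zones as 0-based half-open BED.

    The internal 1-based/exclusive-end convention maps to BED as
    ``bed_start = start - 1``, ``bed_end = end - 1``, preserving the span
    ``end - start``. The name field carries the chromatin class (or
    ``left>right`` for zones); the score field a region's gene count.
    """
    lines = []
    for item in items:
        if isinstance(item, TransitionZone):
            name = f"{item.left_class}>{item.right_class}"
            score = "."
        else:
            name = item.chromatin_class
            score = "." if item.gene_count is None else str(item.gene_count)
        lines.append(f"{item.arm}\t{item.start - 1}\t{item.end - 1}\t{name}\t{score}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_bed(path: str | Path) -> list[ChromatinRegion]:
    """Read a region BED written by :func:`write_bed` back into regions."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        arm, bstart, bend = fields[0], int(fields[1]), int(fields[2])
        cls = fields[3] if len(fields) > 3 else "EU"
        score = fields[4] if len(fields) > 4 else "."
        regions.append(
            ChromatinRegion(
                arm=arm,
                chromatin_class=cls,
                start=bstart + 1,
                end=bend + 1,
                gene_count=None if score == "." else int(score),
            )
        )
    return _sort_and_check(regions)


def agamp3_region_path() -> Path:
    """Path of the packaged AgamP3 boundary table."""
    return Path(
        importlib.resources.files("hetchrom.data") / "agamp3_chromatin_regions.tsv"
    )


def load_agamp3_regions() -> list[ChromatinRegion]:
    """The packaged AgamP3 chromatin boundary map (16 regions, 5 arms)."""
    return read_region_table(agamp3_region_path())
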