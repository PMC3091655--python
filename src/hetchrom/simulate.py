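"""Synthetic chromatin maps, feature intervals, window counts, and GO data.

The generator produces inputs with the statistical structure the analysis
assumes, so every stage can be exercised without genome downloads:

* a chromatin map following the published AgamP3-like layout (the class
  order and size proportions of the five arms, including inter-region
  transition-zone gaps), optionally rescaled;
* feature intervals whose per-class densities and coverage fractions follow
  a configurable table qualitatively mirroring the published medians (gene
  density high in euchromatin; retroelement, tandem-repeat and SD coverage
  concentrated in the heterochromatin types);
* per-window Poisson counts forward-simulated from the log-link model under
  a planted parameter-tying configuration, for partition-recovery studies;
* GO annotations with terms planted at a chosen enrichment factor in the
  study set.

A single master seed streams per-component substreams, so each artifact can
be regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import (
    FEATURE_CLASSES,
    FeatureInterval,
    GenomicWindow,
    WindowFeatureRecord,
    classify_tandem_repeat,
)
from .model import ParameterSet
from .partition import ModelConfig
from .regions import CHROMATIN_CLASSES, ChromatinRegion, load_agamp3_regions

__all__ = [
    "SimulationSpec",
    "DEFAULT_DENSITY",
    "DEFAULT_COVERAGE",
    "default_planted_config",
    "default_planted_params",
    "gen_chromatin_map",
    "gen_feature_intervals",
    "gen_window_counts",
    "gen_go_annotations",
]

#: Target interval densities (count per Mb) per chromatin class and feature.
#: Gene density is high in euchromatin and ~4-5x lower in heterochromatin;
#: repeat densities rise toward the pericentric and diffuse intercalary
#: classes.
DEFAULT_DENSITY: dict[str, dict[str, float]] = {
    "gene":          {"EU": 60, "PEU": 55, "PH": 12, "IHc": 12, "IHd": 15},
    "dna_te":        {"EU": 30, "PEU": 45, "PH": 60, "IHc": 35, "IHd": 60},
    "rna_te":        {"EU": 40, "PEU": 60, "PH": 120, "IHc": 80, "IHd": 100},
    "sd":            {"EU": 3, "PEU": 6, "PH": 5, "IHc": 10, "IHd": 10},
    "microsatellite": {"EU": 25, "PEU": 28, "PH": 40, "IHc": 28, "IHd": 30},
    "minisatellite": {"EU": 15, "PEU": 18, "PH": 35, "IHc": 18, "IHd": 28},
    "satellite":     {"EU": 2, "PEU": 1, "PH": 8, "IHc": 2, "IHd": 5},
    "mar":           {"EU": 10, "PEU": 20, "PH": 16, "IHc": 13, "IHd": 13},
}

#: Target union-coverage fractions per chromatin class and feature.
DEFAULT_COVERAGE: dict[str, dict[str, float]] = {
    "gene":          {"EU": 0.35, "PEU": 0.30, "PH": 0.08, "IHc": 0.08, "IHd": 0.10},
    "dna_te":        {"EU": 0.03, "PEU": 0.045, "PH": 0.06, "IHc": 0.035, "IHd": 0.06},
    "rna_te":        {"EU": 0.06, "PEU": 0.10, "PH": 0.30, "IHc": 0.15, "IHd": 0.25},
    "sd":            {"EU": 0.02, "PEU": 0.05, "PH": 0.04, "IHc": 0.12, "IHd": 0.12},
    "microsatellite": {"EU": 0.005, "PEU": 0.006, "PH": 0.015, "IHc": 0.006, "IHd": 0.008},
    "minisatellite": {"EU": 0.01, "PEU": 0.015, "PH": 0.04, "IHc": 0.015, "IHd": 0.03},
    "satellite":     {"EU": 0.003, "PEU": 0.001, "PH": 0.02, "IHc": 0.003, "IHd": 0.01},
    "mar":           {"EU": 0.03, "PEU": 0.08, "PH": 0.06, "IHc": 0.05, "IHd": 0.05},
}


def default_planted_config(classes: Sequence[str] = CHROMATIN_CLASSES) -> ModelConfig:
    """Planted tying: proximal euchromatin behaves like euchromatin."""
    return ModelConfig.from_merges([["EU", "PEU"]], classes)


def default_planted_params() -> ParameterSet:
    """Well-separated planted parameters (intercept gaps >= 1 on log scale)."""
    mu = {"EU": -6.0, "PEU": -6.0, "PH": -5.0, "IHc": -7.0, "IHd": -4.0}
    beta = {c: 0.3 for c in CHROMATIN_CLASSES}
    zeta = {c: 0.5 for c in CHROMATIN_CLASSES}
    return ParameterSet(mu=mu, beta=beta, zeta=zeta)


@dataclass
class SimulationSpec:
    """Parameters of the synthetic-data generator (seed is mandatory)."""

    seed: int
    template: str = "agamP3-like"
    scale: float = 1.0
    density: dict[str, dict[str, float]] = field(
        default_factory=lambda: {f: dict(v) for f, v in DEFAULT_DENSITY.items()}
    )
    coverage: dict[str, dict[str, float]] = field(
        default_factory=lambda: {f: dict(v) for f, v in DEFAULT_COVERAGE.items()}
    )
    planted_config: ModelConfig = field(default_factory=default_planted_config)
    planted_params: ParameterSet = field(default_factory=default_planted_params)
    length_sigma: float = 0.6  # log-normal shape of interval lengths
    coverage_sigma: float = 0.6  # log-normal jitter of window coverage fractions
    # GO generator
    go_n_genes: int = 5000
    go_n_terms: int = 200
    go_n_study: int = 100
    go_terms_per_gene: float = 2.0  # 1 + Poisson(this) terms per gene
    go_planted_terms: int = 1
    go_enrichment_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for f, per_class in self.coverage.items():
            for c, v in per_class.items():
                if not 0.0 <= v < 1.0:
                    raise ValueError(
                        f"coverage fraction for {f}/{c} must be in [0, 1): {v}"
                    )
        for f, per_class in self.density.items():
            for c, v in per_class.items():
                if v < 0:
                    raise ValueError(f"density for {f}/{c} must be >= 0: {v}")

    def rng(self, component: int) -> np.random.Generator:
        """Independent substream for one generator component."""
        return np.random.default_rng([self.seed, component])


(
    _COMPONENT_MAP,
    _COMPONENT_INTERVALS,
    _COMPONENT_COUNTS,
    _COMPONENT_GO,
    _COMPONENT_WINDOWS,
) = range(5)


def gen_analysis_windows(
    regions: Sequence[ChromatinRegion],
    spec: SimulationSpec,
    eu_window: int = 5_000_000,
    het_window: int = 1_000_000,
) -> list[GenomicWindow]:
    """Tile regions with windows of *varying* length (still exact tiling).

    Real chromatin maps yield window lengths that vary across regions
    because region sizes are not multiples of the target window; that
    within-class length variation is what identifies the length effect beta
    separately from the intercept. This generator reproduces it directly:
    each region is split into windows whose lengths are jittered around the
    target (never exceeding it) but still sum exactly to the region size.
    """
    rng = spec.rng(_COMPONENT_WINDOWS)
    windows: list[GenomicWindow] = []
    for region in regions:
        target = eu_window if region.chromatin_class in ("EU", "PEU") else het_window
        n = max(1, int(np.ceil(region.size / (0.75 * target))))
        u = rng.uniform(0.3, 1.3, size=n)
        lengths = np.floor(region.size * u / u.sum()).astype(int)
        lengths = np.maximum(lengths, 1)
        # distribute the rounding remainder over the first windows
        deficit = region.size - int(lengths.sum())
        for i in range(abs(deficit)):
            lengths[i % n] += 1 if deficit > 0 else -1
        # cap at the target window size, shifting the excess to the shortest
        if n > 1:
            for i in np.flatnonzero(lengths > target):
                excess = int(lengths[i] - target)
                lengths[i] = target
                lengths[int(np.argmin(lengths))] += excess
        pos = region.start
        for ln in lengths:
            windows.append(
                GenomicWindow(
                    arm=region.arm,
                    start=pos,
                    end=pos + int(ln),
                    chromatin_class=region.chromatin_class,
                )
            )
            pos += int(ln)
        assert pos == region.end
    return windows


def gen_chromatin_map(spec: SimulationSpec) -> list[ChromatinRegion]:
    """Chromatin regions following the AgamP3-like layout template.

    Region sizes and the inter-region gaps (transition zones) of the
    template are scaled by ``spec.scale``; class order per arm is preserved
    and the result always satisfies the region-map invariants.
    """
    if spec.template != "agamP3-like":
        raise ValueError(f"unknown layout template {spec.template!r}")
    template = load_agamp3_regions()
    out: list[ChromatinRegion] = []
    by_arm: dict[str, list[ChromatinRegion]] = {}
    for r in template:
        by_arm.setdefault(r.arm, []).append(r)
    for arm, rs in by_arm.items():
        pos, prev_end = 1, 1
        for r in rs:
            gap = max(0, round((r.start - prev_end) * spec.scale))
            pos += gap
            size = max(1, round(r.size * spec.scale))
            out.append(
                ChromatinRegion(
                    arm=arm,
                    chromatin_class=r.chromatin_class,
                    start=pos,
                    end=pos + size,
                )
            )
            pos += size
            prev_end = r.end
    return out


def _place_intervals(
    rng: np.random.Generator,
    region: ChromatinRegion,
    n: int,
    mean_length: float,
    sigma: float,
) -> list[tuple[int, int]]:
    """Place n intervals with log-normal lengths uniformly on the region,
    treating it as a circle so coverage is stationary; wrap-around intervals
    split into two clipped spans."""
    S = region.size
    mu_ln = np.log(max(mean_length, 1.0)) - sigma**2 / 2
    lengths = np.maximum(1, np.round(rng.lognormal(mu_ln, sigma, size=n))).astype(int)
    lengths = np.minimum(lengths, S)
    offsets = rng.integers(0, S, size=n)
    spans: list[tuple[int, int]] = []
    for off, ln in zip(offsets, lengths):
        if off + ln <= S:
            spans.append((region.start + int(off), region.start + int(off + ln)))
        else:
            spans.append((region.start + int(off), region.end))
            spill = int(off + ln - S)
            spans.append((region.start, region.start + spill))
    return spans


def _draw_attributes(
    rng: np.random.Generator, fclass: str, size: int
) -> dict[str, float | int | None]:
    """Attribute values guaranteed to pass the stated post-filters."""
    if fclass == "microsatellite":
        period = int(rng.integers(2, 7))
        copies = float(np.round(rng.uniform(8, 30), 1))
    elif fclass == "minisatellite":
        period = int(rng.integers(7, 100))
        copies = float(np.round(rng.uniform(2, 20), 1))
    elif fclass == "satellite":
        period = int(rng.integers(100, 500))
        copies = float(np.round(rng.uniform(2, 40), 1))
    elif fclass == "sd":
        return {
            "aligned_length": int(max(2500, size)),
            "percent_identity": float(np.round(rng.uniform(90.5, 99.5), 1)),
        }
    else:
        return {}
    return {
        "period": period,
        "copy_number": copies,
        "percent_match": float(np.round(rng.uniform(80, 100), 1)),
    }


def gen_feature_intervals(
    regions: Sequence[ChromatinRegion],
    spec: SimulationSpec,
    feature_classes: Sequence[str] = FEATURE_CLASSES,
) -> list[FeatureInterval]:
    """Feature intervals with per-class densities and coverage targets.

    Interval counts per region are Poisson(density x size); the mean
    interval length is set to -S ln(1 - f) / nu (S the region size, f the
    target coverage fraction, nu the expected count), which under circular
    uniform placement makes the expected union-coverage fraction exactly f.
    """
    rng = spec.rng(_COMPONENT_INTERVALS)
    intervals: list[FeatureInterval] = []
    for region in regions:
        cls = region.chromatin_class
        for fclass in feature_classes:
            density = spec.density.get(fclass, {}).get(cls, 0.0)
            f = spec.coverage.get(fclass, {}).get(cls, 0.0)
            nu = density * region.size / 1e6
            if nu <= 0:
                continue
            n = int(rng.poisson(nu))
            if n == 0:
                continue
            mean_len = -region.size * np.log1p(-f) / nu if f > 0 else 1.0
            for s, e in _place_intervals(rng, region, n, mean_len, spec.length_sigma):
                attrs = _draw_attributes(rng, fclass, e - s)
                iv = FeatureInterval(
                    arm=region.arm, start=s, end=e, feature_class=fclass, **attrs
                )
                if iv.period is not None:
                    assert (
                        classify_tandem_repeat(
                            iv.period, iv.copy_number, iv.percent_match
                        )
                        == fclass
                    )
                intervals.append(iv)
    return intervals


def gen_window_counts(
    windows: Sequence[GenomicWindow],
    spec: SimulationSpec,
    feature: str = "rna_te",
    coverages: Sequence[int] | None = None,
    coverage_offset: float = 1.0,
) -> list[WindowFeatureRecord]:
    """Forward-simulate window counts from the planted log-link model.

    C_i ~ Poisson(exp(mu_g + beta_g ln L_i + zeta_g ln(K_i + 1))) with g the
    planted group of the window's chromatin class. Coverages K_i are taken
    from ``coverages`` if given, otherwise drawn around the class coverage
    target of ``feature`` with multiplicative log-normal jitter (which also
    gives the coverage covariate the within-class variation the fit needs).
    """
    rng = spec.rng(_COMPONENT_COUNTS)
    params = spec.planted_params
    L = np.array([w.length for w in windows], dtype=float)
    if coverages is None:
        frac = np.array(
            [spec.coverage[feature][w.chromatin_class] for w in windows]
        )
        jitter = rng.lognormal(0.0, spec.coverage_sigma, size=len(windows))
        K = np.minimum(np.round(L * frac * jitter), L)
    else:
        K = np.asarray(coverages, dtype=float)
    classes = [w.chromatin_class for w in windows]
    eta = params.linear_predictor(classes, np.log(L), np.log(K + coverage_offset))
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite Poisson rate in forward simulation")
    counts = rng.poisson(np.exp(eta))
    return [
        WindowFeatureRecord(
            window=w, feature_class=feature, count=int(c), coverage=int(k)
        )
        for w, c, k in zip(windows, counts, K)
    ]


def gen_go_annotations(
    spec: SimulationSpec,
) -> tuple[dict[str, frozenset[str]], list[str], list[str]]:
    """GO annotations with terms planted at the requested enrichment factor.

    Returns ``(annotations, study_genes, planted_terms)``. Background term
    frequencies follow a flat Dirichlet draw; the study set is sampled so
    each planted term's study frequency equals ``go_enrichment_factor``
    times its background frequency in expectation (factor 1 leaves the study
    indistinguishable from background; factors below 1 are refused).
    """
    if spec.go_enrichment_factor < 1:
        raise ValueError("enrichment factor must be >= 1 (use a depletion spec)")
    if spec.go_planted_terms > spec.go_n_terms:
        raise ValueError("planted terms exceed the term universe")
    rng = spec.rng(_COMPONENT_GO)
    terms = [f"GO:{i:07d}" for i in range(1, spec.go_n_terms + 1)]
    planted = terms[: spec.go_planted_terms]
    weights = rng.dirichlet(np.ones(spec.go_n_terms))
    genes = [f"gene{i:05d}" for i in range(spec.go_n_genes)]
    ann: dict[str, frozenset[str]] = {}
    for g in genes:
        n_terms = 1 + rng.poisson(spec.go_terms_per_gene)
        n_terms = min(n_terms, spec.go_n_terms)
        chosen = rng.choice(spec.go_n_terms, size=n_terms, replace=False, p=weights)
        ann[g] = frozenset(terms[i] for i in chosen)

    study: set[str] = set()
    pool = set(genes)
    for term in planted:
        carriers = [g for g in genes if term in ann[g]]
        q = len(carriers) / len(genes)
        target_p = min(1.0, spec.go_enrichment_factor * q)
        m = int(rng.binomial(spec.go_n_study, target_p))
        m = min(m, len(carriers))
        chosen = rng.choice(len(carriers), size=m, replace=False)
        study.update(carriers[i] for i in chosen)
        pool -= set(carriers)
    remaining = sorted(pool)
    n_fill = max(0, spec.go_n_study - len(study))
    if n_fill > len(remaining):
        raise ValueError("study size too large for the background")
    fill = rng.choice(len(remaining), size=n_fill, replace=False)
    study.update(remaining[i] for i in fill)
    return ann, sorted(study), planted
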