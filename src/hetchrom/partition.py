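"""Parameter-tying configurations over chromatin classes.

A model configuration ties the five chromatin classes
A = (EU, PH, IHc, PEU, IHd) into parameter groups. In *joint* mode one set
partition is shared by all three regression parameters (intercept mu, length
effect beta, coverage effect zeta), giving Bell(5) = 52 candidate models; in
*independent* mode each parameter carries its own partition and the model
space is the cross-product of the three per-parameter partition lattices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = [
    "ModelConfig",
    "set_partitions",
    "bell_number",
    "enumerate_model_space",
    "support_label",
    "ModelComparison",
    "compare_scores",
]

Partition = tuple[tuple[str, ...], ...]


def _canonical(partition: Sequence[Sequence[str]], order: Sequence[str]) -> Partition:
    """Canonical form: classes sorted within groups, groups by first class."""
    pos = {c: i for i, c in enumerate(order)}
    groups = [tuple(sorted(g, key=pos.__getitem__)) for g in partition]
    seen: set[str] = set()
    for g in groups:
        for c in g:
            if c not in pos:
                raise ValueError(f"unknown class label {c!r}")
            if c in seen:
                raise ValueError(f"class {c!r} assigned to more than one group")
            seen.add(c)
    if seen != set(order):
        raise ValueError(f"partition must cover all of {tuple(order)}")
    return tuple(sorted(groups, key=lambda g: pos[g[0]]))


def set_partitions(labels: Sequence[str]) -> Iterator[Partition]:
    """All set partitions of ``labels`` in canonical form.

    Generated via restricted-growth strings, so the count is the Bell number
    of ``len(labels)`` and no duplicates arise.
    """
    labels = tuple(labels)
    n = len(labels)
    if n == 0:
        yield ()
        return

    def grow(prefix: list[int], kmax: int) -> Iterator[list[int]]:
        if len(prefix) == n:
            yield prefix
            return
        for g in range(kmax + 2):
            yield from grow(prefix + [g], max(kmax, g))

    for rgs in grow([0], 0):
        ngroups = max(rgs) + 1
        groups: list[list[str]] = [[] for _ in range(ngroups)]
        for lab, g in zip(labels, rgs):
            groups[g].append(lab)
        yield _canonical(groups, labels)


def bell_number(n: int) -> int:
    """Bell number B(n) via the triangle recurrence (enumeration oracle)."""
    if n <= 0:
        return 1
    row = [1]
    for _ in range(n - 1):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        row = new
    return row[-1]


@dataclass(frozen=True)
class ModelConfig:
    """A tying of chromatin classes into parameter groups.

    ``mu_partition``, ``beta_partition`` and ``zeta_partition`` are canonical
    set partitions of ``classes``; in joint mode all three coincide.
    """

    classes: tuple[str, ...]
    mu_partition: Partition
    beta_partition: Partition
    zeta_partition: Partition

    @classmethod
    def joint(
        cls, partition: Sequence[Sequence[str]], classes: Sequence[str]
    ) -> "ModelConfig":
        p = _canonical(partition, classes)
        return cls(tuple(classes), p, p, p)

    @classmethod
    def independent(
        cls,
        mu: Sequence[Sequence[str]],
        beta: Sequence[Sequence[str]],
        zeta: Sequence[Sequence[str]],
        classes: Sequence[str],
    ) -> "ModelConfig":
        return cls(
            tuple(classes),
            _canonical(mu, classes),
            _canonical(beta, classes),
            _canonical(zeta, classes),
        )

    @classmethod
    def all_distinct(cls, classes: Sequence[str]) -> "ModelConfig":
        return cls.joint([[c] for c in classes], classes)

    @classmethod
    def from_merges(
        cls, merges: Sequence[Sequence[str]], classes: Sequence[str]
    ) -> "ModelConfig":
        """Joint config from merged groups, e.g. ``[["EU", "PEU"]]`` for the
        retroelement MAX model; unmentioned classes stay singletons."""
        merged = {c for g in merges for c in g}
        parts = [list(g) for g in merges] + [[c] for c in classes if c not in merged]
        return cls.joint(parts, classes)

    @property
    def is_joint(self) -> bool:
        return self.mu_partition == self.beta_partition == self.zeta_partition

    @property
    def n_parameters(self) -> int:
        """Free parameters before any data-driven degeneracy reduction."""
        return (
            len(self.mu_partition)
            + len(self.beta_partition)
            + len(self.zeta_partition)
        )

    def group_of(self, parameter: str, cls_label: str) -> int:
        partition = getattr(self, f"{parameter}_partition")
        for i, g in enumerate(partition):
            if cls_label in g:
                return i
        raise KeyError(cls_label)

    def label(self) -> str:
        def fmt(p: Partition) -> str:
            return "".join("(" + "=".join(g) + ")" for g in p)

        if self.is_joint:
            return fmt(self.mu_partition)
        return (
            f"mu:{fmt(self.mu_partition)}|beta:{fmt(self.beta_partition)}"
            f"|zeta:{fmt(self.zeta_partition)}"
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label()


def enumerate_model_space(
    classes: Sequence[str], mode: str = "joint"
) -> list[ModelConfig]:
    """Enumerate the candidate tying configurations.

    joint: all set partitions shared by (mu, beta, zeta) — Bell(n) models.
    independent: the cross-product of per-parameter partitions — Bell(n)^3
    models; refused above 8 classes (combinatorial blow-up).
    """
    classes = tuple(classes)
    if not 1 <= len(classes) <= 8:
        raise ValueError("between 1 and 8 class labels required")
    if mode == "joint":
        return [ModelConfig.joint(p, classes) for p in set_partitions(classes)]
    if mode == "independent":
        parts = list(set_partitions(classes))
        return [
            ModelConfig(classes, pm, pb, pz)
            for pm, pb, pz in itertools.product(parts, parts, parts)
        ]
    raise ValueError(f"unknown mode {mode!r} (expected 'joint' or 'independent')")


def support_label(delta_bic: float) -> str:
    """Verbal support category for an absolute BIC-score difference.

    < 1.5 mild, 1.5-3 moderate, 3-10 strong, > 10 decisive.
    """
    if delta_bic < 0:
        raise ValueError("delta_bic must be nonnegative")
    if delta_bic < 1.5:
        return "mild"
    if delta_bic <= 3.0:
        return "moderate"
    if delta_bic <= 10.0:
        return "strong"
    return "decisive"


@dataclass(frozen=True)
class ModelComparison:
    """BIC-score comparison of two fitted configurations.

    ``bayes_factor`` approximates the Bayes factor of the favored model over
    the other as exp(delta_bic / 2) with ``delta_bic`` the absolute score
    difference; it is always >= 1.
    """

    label_a: str
    label_b: str
    score_a: float
    score_b: float

    @property
    def delta_bic(self) -> float:
        return abs(self.score_a - self.score_b)

    @property
    def favored(self) -> str:
        return self.label_a if self.score_a >= self.score_b else self.label_b

    @property
    def bayes_factor(self) -> float:
        return math.exp(0.5 * self.delta_bic)

    @property
    def support(self) -> str:
        return support_label(self.delta_bic)


def compare_scores(
    score_a: float, score_b: float, label_a: str = "A", label_b: str = "B"
) -> ModelComparison:
    """Compare two BIC scores (higher is better) directly.

    Useful for working with published per-model scores without refitting.
    """
    return ModelComparison(label_a, label_b, score_a, score_b)
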