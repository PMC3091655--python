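"""GO-term overrepresentation with Bonferroni correction.

A study gene set (e.g. the heterochromatic genes, with transition-zone genes
assigned to the euchromatic background by the caller) is tested term by term
against the background of all GO-annotated genes using the one-sided
hypergeometric upper tail, the standard test of GO term-finder tools. Raw
p-values are Bonferroni-multiplied by the number of terms tested (by default
the terms annotated to at least one study gene); a term is significant when
the corrected p-value is below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneAnnotation",
    "EnrichmentRow",
    "hypergeom_upper_tail",
    "enrich",
    "read_annotations",
    "write_enrichment",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene and its assigned GO terms."""

    gene_id: str
    terms: frozenset[str]
    namespaces: Mapping[str, str] | None = None


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    study_count: int
    study_size: int
    background_count: int
    background_size: int
    p_raw: float
    p_bonferroni: float
    significant: bool
    namespace: str | None = None


def hypergeom_upper_tail(k: int, n: int, K_bg: int, N_bg: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_bg, K_bg, n).

    ``k`` successes in a study draw of size ``n`` from a background of
    ``N_bg`` genes of which ``K_bg`` carry the term.
    """
    if not (0 <= k <= n <= N_bg and 0 <= K_bg <= N_bg):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K_bg={K_bg}, N_bg={N_bg}"
        )
    if k > K_bg:
        raise ValueError(f"k ({k}) cannot exceed background count K_bg ({K_bg})")
    return float(hypergeom.sf(k - 1, N_bg, K_bg, n))


def enrich(
    study_genes: Iterable[str],
    annotations: Mapping[str, frozenset[str] | set[str]] | Sequence[GeneAnnotation],
    background_genes: Iterable[str] | None = None,
    alpha: float = 0.05,
    universe: str = "study",
    namespaces: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided overrepresentation test per GO term.

    Parameters
    ----------
    study_genes : iterable of str
        Must be a subset of the background.
    annotations : mapping gene -> term set, or sequence of GeneAnnotation
    background_genes : iterable of str, optional
        Defaults to every annotated gene.
    universe : {"study", "background"}
        Which terms enter the Bonferroni multiplier: those annotated to at
        least one study gene (term-finder convention, default) or every
        background term.

    Returns a DataFrame of :class:`EnrichmentRow` fields sorted by corrected
    p-value.
    """
    if isinstance(annotations, Mapping):
        ann = {g: frozenset(ts) for g, ts in annotations.items()}
    else:
        ann = {a.gene_id: frozenset(a.terms) for a in annotations}
    background = set(background_genes) if background_genes is not None else set(ann)
    study = set(study_genes)
    missing = sorted(study - background)
    if missing:
        raise ValueError(f"study genes absent from background: {missing}")

    n, N_bg = len(study), len(background)
    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in ann.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    tested = sorted(term_study) if universe == "study" else sorted(term_bg)
    m = len(tested)
    rows = []
    for term in tested:
        k = term_study.get(term, 0)
        K_bg = term_bg[term]
        p = hypergeom_upper_tail(k, n, K_bg, N_bg)
        p_bonf = min(1.0, p * m)
        rows.append(
            EnrichmentRow(
                term=term,
                study_count=k,
                study_size=n,
                background_count=K_bg,
                background_size=N_bg,
                p_raw=p,
                p_bonferroni=p_bonf,
                significant=p_bonf < alpha,
                namespace=namespaces.get(term) if namespaces else None,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows], columns=[
        "term", "study_count", "study_size", "background_count",
        "background_size", "p_raw", "p_bonferroni", "significant", "namespace",
    ])
    return df.sort_values(
        ["p_bonferroni", "p_raw", "term"], kind="mergesort"
    ).reset_index(drop=True)


def read_annotations(path: str | Path) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Read a two/three-column TSV ``gene_id  GO_id  [namespace]``.

    Returns (gene -> term set, term -> namespace).
    """
    genes: dict[str, set[str]] = {}
    ns: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "gene_id":
            continue
        gene, term = parts[0], parts[1]
        genes.setdefault(gene, set()).add(term)
        if len(parts) > 2 and parts[2]:
            ns[term] = parts[2]
    return {g: frozenset(ts) for g, ts in genes.items()}, ns


def write_enrichment(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
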