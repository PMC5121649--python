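"""Annotation readers, identifier translation, and over-representation
analysis (ORA).

Given a query list of identifiers (e.g. the members of one temporal
cluster) and a category structure (GO term -> gene sets from a GAF file,
or KEGG pathway / compound-map memberships from two-column TSV mappings),
ORA tests each category for enrichment with the hypergeometric upper tail

    p = P(X >= m),  X ~ Hypergeometric(N, K, n),

where N is the background size, K the category size, n the annotated query
size and m the overlap.  Multiple testing is controlled by
Benjamini–Hochberg q-values (Bonferroni selectable).

Annotations are used exactly as given in the files — there is no
propagation of memberships up the GO graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .omics import OmicsInputError

__all__ = [
    "AnnotationSet",
    "TranslationDictionary",
    "ORAResult",
    "CategoryResult",
    "read_gaf",
    "read_mapping_tsv",
    "translate_ids",
    "hypergeometric_p",
    "bh_adjust",
    "ora",
    "compound_ora",
]


@dataclass
class AnnotationSet:
    """Category -> member sets over an identifier universe."""

    categories: dict  # category id -> set of member ids
    universe: set
    descriptions: dict = field(default_factory=dict)
    namespace: str = "custom"
    n_skipped_rows: int = 0

    def __post_init__(self):
        for cat, members in self.categories.items():
            if not members:
                raise OmicsInputError(f"category {cat!r} is empty")
            if not members <= self.universe:
                raise OmicsInputError(
                    f"category {cat!r} has members outside the universe"
                )


@dataclass
class TranslationDictionary:
    """One-to-many identifier mapping between two namespaces."""

    source: str
    target: str
    mapping: dict  # id -> sorted list of target ids

    def __post_init__(self):
        self.mapping = {k: sorted(v) for k, v in self.mapping.items() if v}


def read_gaf(path) -> AnnotationSet:
    """Parse a GAF 2.x gene-association file into term -> object-id sets.

    Comment lines start with "!"; rows whose qualifier contains NOT are
    excluded; malformed rows (fewer than 5 tab-separated fields) are
    skipped and counted.  The universe is every object id seen in a kept
    or NOT row.
    """
    categories: dict = {}
    universe: set = set()
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 5 or not fields[1] or not fields[4]:
            skipped += 1
            continue
        obj_id, qualifier, term = fields[1], fields[3], fields[4]
        universe.add(obj_id)
        if "NOT" in qualifier.split("|"):
            continue
        categories.setdefault(term, set()).add(obj_id)
    out = AnnotationSet(categories, universe, namespace="GO")
    out.n_skipped_rows = skipped
    return out


def read_mapping_tsv(path, kind: str = "annotation", namespace: str = "custom"):
    """Read a two-column (identifier, category-or-target [, description])
    TSV as an :class:`AnnotationSet` or a :class:`TranslationDictionary`.
    """
    if kind not in ("annotation", "dictionary"):
        raise OmicsInputError(f"unknown mapping kind {kind!r}")
    pairs = []
    descriptions: dict = {}
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            skipped += 1
            continue
        pairs.append((fields[0], fields[1]))
        if len(fields) >= 3 and fields[2]:
            descriptions[fields[1]] = fields[2]
    if not pairs:
        warnings.warn(f"no usable rows in {path}")
    if kind == "dictionary":
        mapping: dict = {}
        for src, tgt in pairs:
            mapping.setdefault(src, []).append(tgt)
        mapping = {k: sorted(set(v)) for k, v in mapping.items()}
        return TranslationDictionary("source", "target", mapping)
    categories: dict = {}
    universe: set = set()
    for ident, cat in pairs:
        categories.setdefault(cat, set()).add(ident)
        universe.add(ident)
    out = AnnotationSet(categories, universe, descriptions, namespace)
    out.n_skipped_rows = skipped
    return out


def translate_ids(
    ids, dictionary: TranslationDictionary, multi_policy: str = "all"
) -> tuple[dict, list]:
    """Map identifiers through the dictionary.

    Returns (mapping of source -> list of targets, list of unmapped
    identifiers).  ``multi_policy="first"`` keeps only the
    lexicographically first target of one-to-many entries.
    """
    if multi_policy not in ("all", "first"):
        raise OmicsInputError(f"unknown multi_policy {multi_policy!r}")
    mapped: dict = {}
    unmapped: list = []
    for ident in ids:
        targets = dictionary.mapping.get(ident)
        if not targets:
            unmapped.append(ident)
        else:
            mapped[ident] = targets[:1] if multi_policy == "first" else list(targets)
    return mapped, unmapped


def hypergeometric_p(N: int, K: int, n: int, m: int) -> float:
    """Upper tail P(X >= m) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise OmicsInputError(f"require 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not 0 <= m <= min(K, n):
        raise OmicsInputError(f"require 0 <= m <= min(K, n); got m={m}")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    With M tests and sorted p-values p_(1) <= ... <= p_(M),
    q_(i) = min(1, min_{j >= i} p_(j)·M/j), restored to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise OmicsInputError("p-values must lie in [0, 1]")
    M = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * M / np.arange(1, M + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(M)
    q[order] = q_sorted
    return q


@dataclass
class CategoryResult:
    category: str
    description: str
    N: int
    K: int
    n: int
    m: int
    p: float
    q: float
    members: list


@dataclass
class ORAResult:
    """All tested categories plus the subset passing the reporting filter."""

    all_results: list  # every tested category, sorted by (p, category)
    results: list  # q <= fdr_cutoff and m >= min_overlap
    unannotated: list  # query ids outside the background, dropped from n
    n_query_annotated: int
    background_size: int
    adjustment: str = "bh"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "category": r.category,
                    "description": r.description,
                    "N": r.N,
                    "K": r.K,
                    "n": r.n,
                    "m": r.m,
                    "p": r.p,
                    "q": r.q,
                    "members": ";".join(r.members),
                }
                for r in self.all_results
            ]
        )


def ora(
    query,
    annotations: AnnotationSet,
    background=None,
    fdr_cutoff: float = 0.05,
    min_overlap: int = 1,
    adjustment: str = "bh",
) -> ORAResult:
    """Hypergeometric over-representation analysis of a query list.

    The background defaults to the annotation universe; query identifiers
    outside the background are excluded from n and reported, never
    silently dropped.  q-values are BH by default (``adjustment=
    "bonferroni"`` selectable); reported categories satisfy
    q <= fdr_cutoff and overlap >= min_overlap, sorted by p then id.
    """
    query = list(query)
    if not query:
        raise OmicsInputError("empty query")
    if adjustment not in ("bh", "bonferroni"):
        raise OmicsInputError(f"unknown adjustment {adjustment!r}")
    bg = set(background) if background is not None else set(annotations.universe)
    qset = set(query)
    annotated = qset & bg
    unannotated = sorted(qset - bg)
    N, n = len(bg), len(annotated)
    cats = sorted(annotations.categories)
    rows = []
    for cat in cats:
        members = annotations.categories[cat] & bg
        if not members:
            continue
        K = len(members)
        overlap = sorted(annotated & members)
        m = len(overlap)
        p = hypergeometric_p(N, K, n, m)
        rows.append(
            CategoryResult(
                cat,
                annotations.descriptions.get(cat, ""),
                N,
                K,
                n,
                m,
                p,
                np.nan,
                overlap,
            )
        )
    if rows:
        pvals = np.array([r.p for r in rows])
        if adjustment == "bh":
            qvals = bh_adjust(pvals)
        else:
            qvals = np.minimum(1.0, pvals * len(pvals))
        for r, qv in zip(rows, qvals):
            r.q = float(qv)
    rows.sort(key=lambda r: (r.p, r.category))
    reported = [r for r in rows if r.q <= fdr_cutoff and r.m >= min_overlap]
    return ORAResult(rows, reported, unannotated, n, N, adjustment)


def compound_ora(
    compound_ids, compound_annotations: AnnotationSet, **kwargs
) -> ORAResult:
    """ORA of compounds against compound -> map annotations (identical
    mechanics to :func:`ora`)."""
    return ora(compound_ids, compound_annotations, **kwargs)
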