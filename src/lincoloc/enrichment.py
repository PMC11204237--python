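"""Gene-set co-expression enrichment and set-overlap arithmetic.

A library of lincRNA co-expression terms (each term: the ~100 genes most
co-expressed with one lincRNA, GMT format) is queried with a gene set of
interest. Each term is scored by the one-sided Fisher exact test — the
hypergeometric upper tail on the 2×2 table (k, n−k, m−k, N−n−m+k) with
k = |query ∩ term|, n = |query|, m = |term|, N the background universe —
and p-values are Benjamini–Hochberg adjusted across terms.

Absolute p-values depend on the background size N; the default 20,000
approximates the protein-coding gene universe. Symbols are normalised to
upper case with whitespace stripped; no alias resolution is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetLibrary",
    "EnrichmentRow",
    "fisher_enrichment",
    "bh_adjust",
    "overlap_sets",
    "shared_fraction",
]


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class GeneSetLibrary:
    """Named gene sets (term → member symbols) over a fixed background."""

    terms: dict[str, frozenset[str]]
    background_size: int = 20_000

    def __post_init__(self) -> None:
        if self.background_size <= 0:
            raise ValueError("background_size must be positive")
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.terms.items():
            normed = frozenset(_norm(m) for m in members if m.strip())
            if not normed:
                raise ValueError(f"term {name!r} is empty")
            clean[name] = normed
        self.terms = clean

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_gmt(cls, path: str | Path, background_size: int = 20_000) -> "GeneSetLibrary":
        terms: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs term, description and >=1 member"
                    )
                terms[fields[0]] = frozenset(_norm(m) for m in fields[2:] if m.strip())
        return cls(terms, background_size=background_size)

    def to_gmt(self, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.terms):
                desc = (descriptions or {}).get(name, "")
                fh.write("\t".join([name, desc] + sorted(self.terms[name])) + "\n")


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    overlap_k: int
    term_size_m: int
    query_size_n: int
    p_raw: float
    p_adjusted: float
    overlapping_genes: frozenset[str]

    @property
    def overlap_label(self) -> str:
        """The conventional 'k/m' overlap display, e.g. '55/100'."""
        return f"{self.overlap_k}/{self.term_size_m}"


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def fisher_enrichment(
    query: Iterable[str], library: GeneSetLibrary
) -> list[EnrichmentRow]:
    """Score every library term against a query gene set.

    Returns rows sorted by adjusted p (ties: raw p, then term name).
    Raises if the query is empty or the background cannot hold the union of
    query and term.
    """
    qset = frozenset(_norm(g) for g in query if g.strip())
    if not qset:
        raise ValueError("query gene set is empty")
    N = library.background_size
    n = len(qset)
    names, praw, ks, ms, ovls = [], [], [], [], []
    for name, members in library.terms.items():
        m = len(members)
        union = len(qset | members)
        if N < union:
            raise ValueError(
                f"background_size {N} smaller than |query ∪ term| = {union} for term {name!r}"
            )
        overlap = qset & members
        k = len(overlap)
        # hypergeometric upper tail P(X >= k): Fisher exact, one-sided
        p = float(_st.hypergeom.sf(k - 1, N, m, n))
        names.append(name)
        praw.append(min(p, 1.0))
        ks.append(k)
        ms.append(m)
        ovls.append(frozenset(overlap))
    padj = bh_adjust(praw)
    rows = [
        EnrichmentRow(name, k, m, n, p, q, ov)
        for name, k, m, p, q, ov in zip(names, ks, ms, praw, padj, ovls)
    ]
    rows.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "overlap": [r.overlap_label for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "genes": [";".join(sorted(r.overlapping_genes)) for r in rows],
        }
    )


def overlap_sets(sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Venn partition of 2 or 3 named gene sets.

    Returns one row per exclusive region (keyed by the '&'-joined member
    names) plus one row per pairwise intersection (prefixed 'pair:'). More
    than three sets is unsupported.
    """
    named = {k: frozenset(_norm(g) for g in v) for k, v in sets.items()}
    if not 2 <= len(named) <= 3:
        raise ValueError("overlap_sets supports exactly 2 or 3 sets")
    names = list(named)
    universe = frozenset().union(*named.values())
    rows = []
    # exclusive Venn regions: every non-empty membership pattern
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = frozenset.intersection(*(named[c] for c in combo))
            outside = [named[c] for c in names if c not in combo]
            exclusive = inside.difference(*outside) if outside else inside
            rows.append({"region": "&".join(combo), "kind": "exclusive", "count": len(exclusive)})
    for a, b in combinations(names, 2):
        rows.append(
            {"region": f"pair:{a}&{b}", "kind": "intersection", "count": len(named[a] & named[b])}
        )
    rows.append({"region": "union", "kind": "union", "count": len(universe)})
    return pd.DataFrame(rows)


def shared_fraction(shared: int, total: int) -> int:
    """Percentage of a total that is shared, rounded to whole percent.

    ``shared_fraction(177, 312) == 57``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= shared <= total:
        raise ValueError("need 0 <= shared <= total")
    return int(math.floor(100.0 * shared / total + 0.5))
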