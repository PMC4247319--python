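"""Hypergeometric over-representation of a gene set against annotation terms.

Given a query of n distinct genes drawn from a universe of N genes, a term
with K annotated members and overlap k with the query is scored by the
upper-tail hypergeometric probability P(X >= k).  Raw p-values are reported
(with an informational Benjamini-Hochberg column); only terms with k >= 1
are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class Term:
    term_id: str
    description: str
    class_label: str
    members: frozenset


@dataclass
class AnnotationCollection:
    """A list of annotation terms plus the declared gene universe."""

    terms: list[Term]
    universe: frozenset

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate term ids in annotation collection")
        for t in self.terms:
            if not t.members:
                raise DataError(f"term {t.term_id!r} has no members")
            if not t.members <= self.universe:
                raise DataError(f"term {t.term_id!r} has members outside the universe")


def read_annotations(path: str | Path) -> AnnotationCollection:
    """Read a GMT-like TSV: term, description, class, then member genes.

    Lines starting with ``#`` are comments.  The universe is the union of
    all member genes (callers may intersect it with the assayed genes).
    """
    terms: list[Term] = []
    universe: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}: need term, description, class and >= 1 member")
            members = frozenset(g.strip() for g in parts[3:] if g.strip())
            terms.append(Term(parts[0], parts[1], parts[2], members))
            universe |= members
    return AnnotationCollection(terms, frozenset(universe))


def write_annotations(collection: AnnotationCollection, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for t in collection.terms:
            fh.write("\t".join([t.term_id, t.description, t.class_label,
                                *sorted(t.members)]) + "\n")
    return path


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed with numerically stable log-combinatorics (scipy survival
    function).  Parameter contract: 0 <= K <= N, 0 <= n <= N,
    0 <= k <= min(K, n).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ParameterError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(query, collection: AnnotationCollection,
           p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Over-representation table of the query set against every term.

    The query is deduplicated and intersected with the universe (genes
    outside the universe are dropped with a logged count).  One row per
    term with overlap >= 1, sorted by p ascending; ``significant`` flags
    raw p < ``p_threshold`` and ``p_bh`` is informational.
    """
    if not 0 < p_threshold <= 1:
        raise ParameterError("p_threshold must be in (0, 1]")
    q = {str(g) for g in query}
    dropped = len(q - collection.universe)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)
    q &= collection.universe
    cols = ["term", "description", "class", "N", "K", "n", "k", "p",
            "p_bh", "significant", "overlap"]
    if not q:
        import warnings
        warnings.warn("query empty after universe intersection", UserWarning, stacklevel=2)
        return pd.DataFrame(columns=cols)
    N, n = len(collection.universe), len(q)
    rows = []
    for t in collection.terms:
        overlap = sorted(q & t.members)
        k = len(overlap)
        if k < 1:
            continue
        rows.append({
            "term": t.term_id, "description": t.description, "class": t.class_label,
            "N": N, "K": len(t.members), "n": n, "k": k,
            "p": hypergeom_pvalue(N, len(t.members), n, k),
            "overlap": ";".join(overlap),
        })
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows).sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < p_threshold
    return out[cols]
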