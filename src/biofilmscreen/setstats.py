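"""Gene-set overlap, three-way Venn partitions, and category enrichment.

Overlap significance uses the hypergeometric upper tail: the probability of
drawing at least the observed intersection when one set is sampled from a
finite gene universe.  Category enrichment applies the same test per
category with Bonferroni (default) or Benjamini-Hochberg correction, and
collapses categories that annotate identical gene subsets onto the
lowest-p representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _normalize_id(gene: str) -> str:
    return str(gene).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of unique, case-normalized gene identifiers."""

    label: str
    members: frozenset = field(default_factory=frozenset)

    def __init__(self, label: str, members):
        object.__setattr__(self, "label", label)
        object.__setattr__(
            self, "members", frozenset(_normalize_id(g) for g in members)
        )

    def __len__(self):
        return len(self.members)

    def __contains__(self, gene):
        return _normalize_id(gene) in self.members


@dataclass(frozen=True)
class OverlapResult:
    label_a: str
    label_b: str
    size_a: int
    size_b: int
    universe_size: int
    intersection_size: int
    percent_of_a: float        # full precision; round for display
    expected_overlap: float    # size_a * size_b / universe_size
    p_value: float             # hypergeometric upper tail


def hypergeom_overlap_test(
    size_a: int, size_b: int, universe_size: int, intersection: int
) -> float:
    """P(X ≥ intersection) for the overlap of two sets in a finite universe.

    X ~ Hypergeometric(N=universe_size, K=size_a, n=size_b): the overlap
    obtained when set b is drawn uniformly from the universe given set a.
    """
    if universe_size < 0 or size_a < 0 or size_b < 0 or intersection < 0:
        raise ValueError("all arguments must be non-negative")
    if size_a > universe_size or size_b > universe_size:
        raise ValueError("set sizes must not exceed the universe size")
    if intersection > min(size_a, size_b):
        raise ValueError("intersection cannot exceed the smaller set")
    if intersection < size_a + size_b - universe_size:
        raise ValueError("intersection below the feasible minimum")
    return float(stats.hypergeom.sf(intersection - 1, universe_size, size_a, size_b))


def overlap(a: GeneSet, b: GeneSet, universe_size: int, universe: GeneSet | None = None) -> OverlapResult:
    """Intersection statistics for two gene sets in a common universe.

    ``percent_of_a`` is 100 · |a ∩ b| / |a| (stored at full precision;
    display rounds to integer); ``expected_overlap`` is the chance
    expectation |a||b|/N; the p-value is the hypergeometric upper tail.
    If an explicit ``universe`` set is supplied, members of a or b outside
    it are an error.
    """
    if universe is not None:
        stray = sorted((a.members | b.members) - universe.members)
        if stray:
            raise ValueError(f"gene(s) absent from the universe: {stray[:10]}")
        if universe_size != len(universe):
            universe_size = len(universe)
    inter = len(a.members & b.members)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set sizes must not exceed the universe size")
    return OverlapResult(
        label_a=a.label,
        label_b=b.label,
        size_a=len(a),
        size_b=len(b),
        universe_size=universe_size,
        intersection_size=inter,
        percent_of_a=100.0 * inter / len(a) if len(a) else float("nan"),
        expected_overlap=len(a) * len(b) / universe_size if universe_size else float("nan"),
        p_value=hypergeom_overlap_test(len(a), len(b), universe_size, inter),
    )


def venn3(a: GeneSet, b: GeneSet, c: GeneSet) -> dict:
    """Counts of the 7 exclusive regions of a three-set Venn diagram.

    Keys name membership by set label combination, e.g. ``"a_only"``,
    ``"ab"``, ``"abc"``; region counts sum to |a ∪ b ∪ c| and each input
    set size equals the sum of its four regions.
    """
    A, B, C = a.members, b.members, c.members
    return {
        "a_only": len(A - B - C),
        "b_only": len(B - A - C),
        "c_only": len(C - A - B),
        "ab": len((A & B) - C),
        "ac": len((A & C) - B),
        "bc": len((B & C) - A),
        "abc": len(A & B & C),
        "labels": (a.label, b.label, c.label),
    }


def enrich_categories(
    gene_set: GeneSet,
    annotation: dict,
    universe: GeneSet,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric category enrichment of a gene set against a universe.

    Parameters
    ----------
    gene_set : GeneSet
        Genes of interest; must be a subset of the universe.
    annotation : dict
        Mapping gene → category or gene → iterable of categories.
        Unannotated universe genes are allowed and counted in N.
    universe : GeneSet
        All genes the set was drawn from (e.g. every strain screened).
    correction : {"none", "bonferroni", "benjamini-hochberg"}
        Multiple-testing correction across categories.

    Returns
    -------
    DataFrame
        Per category: ``category, k`` (set genes in category), ``K``
        (universe genes in category), ``n`` (set size), ``N`` (universe
        size), ``p_raw, p_adjusted, method``, sorted by p_raw.  Categories
        annotating identical gene subsets of the universe are collapsed to
        one row (lowest p, ties by name).
    """
    if not len(gene_set) or not len(universe):
        raise ValueError("gene set and universe must be non-empty")
    stray = sorted(gene_set.members - universe.members)
    if stray:
        raise ValueError(f"gene(s) absent from the universe: {stray[:10]}")
    if correction not in ("none", "bonferroni", "benjamini-hochberg"):
        raise ValueError(f"unknown correction {correction!r}")

    by_category: dict[str, set] = {}
    for gene, cats in annotation.items():
        g = _normalize_id(gene)
        if g not in universe.members:
            continue
        if isinstance(cats, str):
            cats = [cats]
        for cat in cats:
            by_category.setdefault(str(cat), set()).add(g)

    N, n = len(universe), len(gene_set)
    rows = []
    for cat, genes in by_category.items():
        K = len(genes)
        k = len(genes & gene_set.members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {"category": cat, "k": k, "K": K, "n": n, "N": N, "p_raw": p,
             "members_key": frozenset(genes)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["category", "k", "K", "n", "N", "p_raw", "p_adjusted", "method"]
        )
    df = pd.DataFrame(rows)
    # categories capturing identical universe gene subsets -> one representative
    df = (
        df.sort_values(["p_raw", "category"])
        .drop_duplicates(subset="members_key", keep="first")
        .drop(columns="members_key")
        .reset_index(drop=True)
    )
    if correction == "none":
        df["p_adjusted"] = df["p_raw"]
    elif correction == "bonferroni":
        df["p_adjusted"] = np.minimum(1.0, len(df) * df["p_raw"])
    else:
        df["p_adjusted"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    df["method"] = correction
    return df.sort_values(["p_raw", "category"]).reset_index(drop=True)
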