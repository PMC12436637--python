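"""Gene-set comparison statistics.

Hypergeometric overlap between hit lists (screen vs screen, screen vs
published external screens) and term/complex over-representation against
GMT collections. All tests are exact upper-tail hypergeometric
probabilities; p-value batches are BH-adjusted. Cross-study comparisons
condition on the genes analysed in *both* studies — every external list
must carry its own analysed-gene universe, and a silent global-universe
substitution is refused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cargoscreen")

_COMPARATORS: dict[str, Callable[[float, float], bool]] = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
}


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two gene sets inside a shared universe."""

    n_a: int
    n_b: int
    n_universe: int
    overlap: int
    expected: float
    fold: float
    p: float
    q: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b, "n_universe": self.n_universe,
            "overlap": self.overlap, "expected": self.expected,
            "fold": self.fold, "p": self.p, "q": self.q,
        }


def hypergeom_overlap(
    a: Iterable[str], b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Upper-tail hypergeometric test for |A intersect B|.

    A and B are intersected with the universe first;
    p = P(X >= k) for X ~ Hypergeometric(N, |A|, |B|). k = 0 gives p = 1
    exactly, and the test is symmetric in A and B.
    """
    u = {g.upper() for g in universe}
    if not u:
        raise ValueError("empty universe")
    sa = {g.upper() for g in a} & u
    sb = {g.upper() for g in b} & u
    k = len(sa & sb)
    n, ka, kb = len(u), len(sa), len(sb)
    p = float(sps.hypergeom.sf(k - 1, n, ka, kb))
    expected = ka * kb / n
    fold = k / expected if expected > 0 else np.nan
    return OverlapResult(ka, kb, n, k, expected, fold, min(p, 1.0))


def multi_screen_matrix(
    hit_sets: Mapping[str, set[str]],
    external_sets: Mapping[str, tuple[set[str], set[str]]],
    own_universe: set[str],
) -> pd.DataFrame:
    """All-pairs overlap of this study's hit sets against external screens.

    ``external_sets`` maps name -> (hits, analysed-gene universe); per pair
    the test conditions on the intersection of the two studies' analysed
    genes. BH FDR across the whole matrix. An external set without a
    universe is an error.
    """
    rows = []
    for a_name, a_set in hit_sets.items():
        for b_name, payload in external_sets.items():
            if not isinstance(payload, tuple) or len(payload) != 2:
                raise ValueError(
                    f"external set {b_name!r} must carry (hits, universe)")
            b_set, b_universe = payload
            if not b_universe:
                raise ValueError(
                    f"external set {b_name!r} lacks an analysed-gene universe")
            shared = {g.upper() for g in own_universe} & {
                g.upper() for g in b_universe}
            res = hypergeom_overlap(a_set, b_set, shared)
            rows.append({"set_a": a_name, "set_b": b_name, **res.as_dict()})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def external_threshold_filter(
    records: pd.DataFrame, rule: tuple[str, str, float]
) -> set[str]:
    """Declarative hit definition for external screens.

    ``rule`` is (field, comparator, threshold), e.g. ("fdr", "<", 0.05) for
    CRISPR screens or ("chi2_probability", ">=", 0.95) for the RNAi screen
    convention. Records must carry a ``gene`` column and the named field.
    """
    field, cmp_name, threshold = rule
    if cmp_name not in _COMPARATORS:
        raise ValueError(f"unknown comparator {cmp_name!r}")
    if len(records) == 0:
        logger.warning("external record table is empty")
        return set()
    if field not in records.columns:
        raise KeyError(f"records lack field {field!r}")
    cmp = _COMPARATORS[cmp_name]
    keep = records[records[field].map(lambda v: cmp(float(v), threshold))]
    return {g.upper() for g in keep["gene"]}


def term_enrichment(
    query: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
    significance_tiers: Sequence[float] = (0.05, 0.01, 0.001),
    min_size: int = 3,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against a GMT
    collection.

    Terms are intersected with the universe and size-filtered before
    testing; BH FDR across the collection; star tiers (*, **, ***) at the
    configured q cutoffs. Per-term query members are listed so membership
    heat maps can be rebuilt from the table.
    """
    u = {g.upper() for g in universe}
    q_set = {g.upper() for g in query} & u
    rows = []
    for name in sorted(annotation):
        members = {g.upper() for g in annotation[name]} & u
        if not min_size <= len(members) <= max_size:
            continue
        k = len(members & q_set)
        p = float(sps.hypergeom.sf(k - 1, len(u), len(members), len(q_set)))
        rows.append({
            "term": name,
            "term_size": len(members),
            "query_size": len(q_set),
            "overlap": k,
            "p": min(p, 1.0),
            "members_in_query": ",".join(sorted(members & q_set)),
        })
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return table
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    tiers = sorted(significance_tiers, reverse=True)  # loosest first
    stars = []
    for qv in table["q"]:
        s = ""
        for i, tier in enumerate(tiers, start=1):
            if qv < tier:
                s = "*" * i
        stars.append(s)
    table["stars"] = stars
    return table.sort_values(["p", "term"], kind="mergesort").reset_index(
        drop=True)
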