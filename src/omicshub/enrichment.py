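"""Gene-family overrepresentation by the one-sided hypergeometric test.

For a query set of n genes drawn from a universe of N annotated genes, a
family with m members overlapping the query in k genes gets the enrichment
tail probability

    p = P(X >= k),  X ~ Hypergeometric(N, m, n)

(the Fisher exact enrichment tail). Families with p below ``alpha``
(default 0.01) are flagged as overrepresented. No multiple-testing
correction is applied by default; Benjamini-Hochberg is available behind a
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["FamilyAnnotation", "EnrichmentResult", "enrich_families",
           "hypergeom_enrichment_p"]


class EmptyUniverseError(ValueError):
    pass


@dataclass
class FamilyAnnotation:
    """Family name -> member gene IDs, with the annotated gene universe.

    Families may overlap. Every member must belong to the universe; by
    default the universe is the union of all family members.
    """

    families: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.families.values()) if self.families else set()
        stray = {
            f: members - self.universe
            for f, members in self.families.items()
            if members - self.universe
        }
        if stray:
            raise ValueError(
                f"family member(s) outside the universe: {sorted(stray)[:3]}"
            )

    @classmethod
    def from_gmt(cls, path) -> "FamilyAnnotation":
        """Read a GMT-like file: name <tab> description <tab> member..."""
        families: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                families[parts[0]] = {p.strip() for p in parts[2:] if p.strip()}
        return cls(families=families)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.families):
                members = "\t".join(sorted(self.families[name]))
                fh.write(f"{name}\tna\t{members}\n")


@dataclass(frozen=True)
class EnrichmentResult:
    family_name: str
    k: int  # overlap count
    n: int  # query size (within universe)
    m: int  # family size
    N: int  # universe size
    p_value: float
    enriched: bool


def hypergeom_enrichment_p(k: int, N: int, m: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, m, n)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def enrich_families(
    query: Iterable[str],
    ann: FamilyAnnotation,
    alpha: float = 0.01,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """Overrepresentation test of every family against the query set.

    Query members outside the universe are dropped (count logged). Results
    are sorted by p-value then family name.
    """
    if not ann.universe:
        raise EmptyUniverseError("annotation universe is empty")
    q = {str(x).strip() for x in query}
    dropped = q - ann.universe
    if dropped:
        logger.info("dropped %d query id(s) outside the universe", len(dropped))
    q &= ann.universe
    N, n = len(ann.universe), len(q)
    raw = []
    for name, members in ann.families.items():
        k, m = len(q & members), len(members)
        raw.append((name, k, m, hypergeom_enrichment_p(k, N, m, n)))
    if bh and raw:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r[3] for r in raw], method="fdr_bh")[1]
        raw = [(name, k, m, p_adj) for (name, k, m, _), p_adj in zip(raw, adj)]
    results = [
        EnrichmentResult(
            family_name=name, k=k, n=n, m=m, N=N, p_value=p,
            enriched=p < alpha,
        )
        for name, k, m, p in raw
    ]
    results.sort(key=lambda r: (r.p_value, r.family_name))
    return results
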