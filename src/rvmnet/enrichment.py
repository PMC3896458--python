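"""Gene-set over-representation with the enrichment ratio Re and an
empirical FDR derived from the Fisher-vs-chi-square comparison.

Each term is tested against the up-regulated and down-regulated gene lists
separately with a two-sided Fisher exact test and a Pearson chi-square test
(no continuity correction) on the 2x2 table

    (nf, n - nf)            nf flagged genes in the category, n genes in it
    (Nf - nf, N - n - Nf + nf)   Nf flagged genes on the array of N genes.

The enrichment ratio Re = (nf/n) / (Nf/N) compares the category's flagged
proportion with the array-wide proportion; the signed enrichment score is
+Re for the up batch and -Re for the down batch. The batch-level empirical
FDR is 1 - Nk/T, where Nk counts terms whose Fisher p is smaller than the
paired chi-square p out of T terms tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "term_id", "name", "category", "direction_class",
    "nf", "n", "Nf", "N", "fisher_p", "chi2_p",
    "Re", "score", "neg_log10_p", "fdr", "significant",
]

CATEGORIES = ("GO", "pathway")


@dataclass
class GeneSetCollection:
    """Term -> (name, category, members) mapping over a measured gene universe."""

    terms: dict[str, tuple[str, str, frozenset[str]]]
    universe: frozenset[str]

    def restricted(self, universe=None) -> "GeneSetCollection":
        """Intersect every term with *universe* and drop terms left empty."""
        uni = frozenset(universe) if universe is not None else self.universe
        restricted = {}
        for tid, (name, cat, members) in self.terms.items():
            kept = frozenset(members) & uni
            if kept:
                restricted[tid] = (name, cat, kept)
        return GeneSetCollection(terms=restricted, universe=uni)

    def of_category(self, category: str) -> "GeneSetCollection":
        return GeneSetCollection(
            terms={t: v for t, v in self.terms.items() if v[1] == category},
            universe=self.universe,
        )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one term: flagged-in-category vs the rest of the array."""

    nf: int
    n: int
    Nf: int
    N: int

    def __post_init__(self) -> None:
        cells = self.cells()
        if self.n > self.N or self.Nf > self.N or any(c < 0 for c in cells):
            raise InvalidInputError(f"inconsistent 2x2 margins: {self}")

    def cells(self) -> tuple[int, int, int, int]:
        """(nf, n-nf, Nf-nf, N-n-Nf+nf) row-major."""
        return (self.nf, self.n - self.nf, self.Nf - self.nf, self.N - self.n - self.Nf + self.nf)


@dataclass(frozen=True)
class EmpiricalFDRResult:
    """FDR = 1 - Nk/T over a batch of T terms; Nk = #{Fisher p < chi2 p}."""

    T: int
    Nk: int

    @property
    def fdr(self) -> float:
        return 1.0 - self.Nk / self.T


def make_table(term_genes, flagged, universe) -> ContingencyTable:
    """Build the 2x2 table for one term against one flagged gene list."""
    term_genes, flagged, universe = set(term_genes), set(flagged), set(universe)
    outside = (term_genes | flagged) - universe
    if outside:
        raise InvalidInputError(f"genes outside the universe: {sorted(outside)[:5]}")
    return ContingencyTable(
        nf=len(term_genes & flagged), n=len(term_genes), Nf=len(flagged), N=len(universe)
    )


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: total probability of tables with the same
    margins whose probability does not exceed the observed table's.

    Computed in exact integer arithmetic: table probabilities share the
    denominator C(N, Nf), so comparing integer hypergeometric weights
    C(n, k) * C(N-n, Nf-k) against the observed weight decides ties exactly
    (no floating-point tie tolerance). Degenerate margins give p = 1.
    """
    N, n, Nf, nf = table.N, table.n, table.Nf, table.nf
    lo, hi = max(0, n + Nf - N), min(n, Nf)
    weights = [comb(n, k) * comb(N - n, Nf - k) for k in range(lo, hi + 1)]
    w_obs = weights[nf - lo]
    tail = sum(w for w in weights if w <= w_obs)
    return min(tail / comb(N, Nf), 1.0)


def chi2_test(table: ContingencyTable) -> float:
    """Pearson chi-square p (1 df, no Yates correction); p = 1 on a zero margin."""
    a, b, c, d = table.cells()
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        logger.warning("chi-square statistic undefined for zero margin in %s; p = 1", table)
        return 1.0
    stat = table.N * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(stat, df=1))


def enrichment_ratio(table: ContingencyTable) -> float:
    """Re = (nf/n) / (Nf/N); 1 when the category matches the array proportion."""
    if table.n == 0 or table.Nf == 0:
        raise InvalidInputError(f"Re undefined for n={table.n}, Nf={table.Nf}")
    return (table.nf / table.n) / (table.Nf / table.N)


def empirical_fdr(fisher_ps, chi2_ps) -> EmpiricalFDRResult:
    """Batch FDR = 1 - Nk/T from paired Fisher / chi-square p-values."""
    f = np.asarray(fisher_ps, dtype=float)
    c = np.asarray(chi2_ps, dtype=float)
    if f.shape != c.shape or f.ndim != 1 or f.size == 0:
        raise InvalidInputError("fisher and chi2 p-value sequences must be paired, equal length >= 1")
    return EmpiricalFDRResult(T=int(f.size), Nk=int(np.sum(f < c)))


def _test_batch(collection: GeneSetCollection, flagged: set[str],
                direction_class: str, alpha: float) -> pd.DataFrame:
    rows = []
    for tid, (name, cat, members) in collection.terms.items():
        table = make_table(members, flagged, collection.universe)
        fp = fisher_two_sided(table)
        cp = chi2_test(table)
        re = enrichment_ratio(table)
        rows.append({
            "term_id": tid, "name": name, "category": cat,
            "direction_class": direction_class,
            "nf": table.nf, "n": table.n, "Nf": table.Nf, "N": table.N,
            "fisher_p": fp, "chi2_p": cp, "Re": re,
            "score": re if direction_class == "up" else -re,
            "neg_log10_p": -np.log10(fp) if fp > 0 else np.inf,
            "significant": fp < alpha,
        })
    df = pd.DataFrame(rows)
    df["fdr"] = empirical_fdr(df["fisher_p"], df["chi2_p"]).fdr
    ascending = direction_class == "down"  # up: score desc; down: score asc
    return df.sort_values(["score", "term_id"], ascending=[ascending, True],
                          kind="mergesort").reset_index(drop=True)[ENRICHMENT_COLUMNS]


def run_enrichment(collection: GeneSetCollection, up, down, alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of every term in the up list and the down list.

    Terms are first restricted to the measured universe. Returns the up
    batch (sorted by score descending) stacked above the down batch (score
    ascending); a term can therefore appear twice, once per batch. An empty
    flagged list yields an empty batch with a warning.
    """
    up, down = set(up), set(down)
    if up & down:
        raise InvalidInputError(f"up and down lists overlap: {sorted(up & down)[:5]}")
    collection = collection.restricted()
    batches = []
    for direction_class, flagged in (("up", up), ("down", down)):
        if not flagged:
            logger.warning("empty %s gene list: skipping that enrichment batch", direction_class)
            continue
        if not flagged <= collection.universe:
            raise InvalidInputError("flagged genes outside the universe")
        if collection.terms:
            batches.append(_test_batch(collection, flagged, direction_class, alpha))
    if not batches:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(batches, ignore_index=True)
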