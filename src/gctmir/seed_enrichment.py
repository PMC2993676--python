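"""MicroRNA seed-complementary-region (SCR) enrichment in 3'UTRs.

A microRNA's 2-7nt seed (positions 2-7 of the mature sequence) defines a
6-mer whose reverse complement — the SCR — marks candidate target sites
in mRNA 3'UTRs.  Enrichment of SCR-carrying genes among a down-regulated
set, relative to the array background, is assessed with a 2x2 Pearson
chi-squared test (1 df, two-tailed); the Yates continuity correction is
off by default and available by flag.  A gene counts once however many
times the hexamer occurs, and a gene carries the SCR if any supplied UTR
isoform contains it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .io_core import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "SeedEnrichmentResult",
    "seed_to_scr",
    "extract_seed",
    "genes_with_scr",
    "chi_squared_2x2",
    "scr_enrichment",
    "intersect_gene_lists",
]


@dataclass
class SeedEnrichmentResult:
    """2x2 SCR contingency counts with the chi-squared statistic.

    a/b: down-regulated genes with/without the SCR; c/d: background genes
    with/without (by default the background includes the down-regulated
    genes, matching the 'overall presence on the array' framing).
    """

    scr: str
    a: int
    b: int
    c: int
    d: int
    chi_squared: float
    p_two_tailed: float

    @property
    def proportion_down(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def proportion_background(self) -> float:
        return self.c / (self.c + self.d)


def _validate_hexamer(word: str, what: str) -> str:
    w = word.upper().replace("U", "T")
    if len(w) != 6:
        raise ValueError(f"{what} must be exactly 6 nt, got {len(word)}")
    if set(w) - set("ACGT"):
        raise ValueError(f"{what} contains characters outside A/C/G/T/U")
    return w


def seed_to_scr(seed_2to7: str) -> str:
    """Reverse-complement a 6-nt seed into its DNA seed-complementary region."""
    return reverse_complement(_validate_hexamer(seed_2to7, "seed"))


def extract_seed(mature_mir: str) -> str:
    """2-7nt seed of a mature microRNA (1-based positions 2-7 inclusive)."""
    if len(mature_mir) < 7:
        raise ValueError("mature microRNA must be at least 7 nt")
    return mature_mir[1:7].upper()


def genes_with_scr(utrs: list[SequenceRecord], gene_set: set[str],
                   scr: str) -> tuple[int, int, list[str]]:
    """Count genes in the set whose 3'UTR contains the SCR at least once.

    UTR records are keyed by gene id; multiple isoforms per gene are
    allowed (carrier if any isoform contains the hexamer).  Genes with
    no UTR record are excluded from both counts and returned separately.
    """
    scr = _validate_hexamer(scr, "SCR")
    carriers: dict[str, bool] = {}
    for rec in utrs:
        if rec.id in gene_set:
            carriers[rec.id] = carriers.get(rec.id, False) or (scr in rec.sequence)
    lacking = sorted(g for g in gene_set if g not in carriers)
    with_ = sum(carriers.values())
    return with_, len(carriers) - with_, lacking


def chi_squared_2x2(a: int, b: int, c: int, d: int,
                    continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-squared (1 df) on a 2x2 table; two-tailed p.

    Yates continuity correction is applied when ``continuity`` is set.
    A zero row or column margin is a degenerate table.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate table: zero margin")
    if a + b + c + d >= 2 and (a * d == b * c):
        # no association at all; chi2_contingency handles it but be explicit
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=continuity)
    return float(chi2), float(p)


def scr_enrichment(down_genes: set[str], background_genes: set[str],
                   utrs: list[SequenceRecord], scr: str,
                   continuity: bool = False,
                   disjoint_background: bool = False) -> SeedEnrichmentResult:
    """Test SCR enrichment in down-regulated genes' 3'UTRs versus background.

    ``down_genes`` must be a subset of ``background_genes``.  By default
    the background row of the contingency table is the *full* background
    (down-regulated genes included); set ``disjoint_background`` to
    compare against background-only genes instead.
    """
    if not down_genes:
        raise ValueError("down-regulated gene set is empty")
    if not down_genes <= background_genes:
        raise ValueError("down-regulated genes must be a subset of the background")
    a, b, lack_down = genes_with_scr(utrs, down_genes, scr)
    bg = background_genes - down_genes if disjoint_background else background_genes
    c, d, lack_bg = genes_with_scr(utrs, bg, scr)
    if lack_down or lack_bg:
        logger.info("genes lacking UTR records: %d down, %d background",
                    len(lack_down), len(lack_bg))
    chi2, p = chi_squared_2x2(a, b, c, d, continuity=continuity)
    return SeedEnrichmentResult(_validate_hexamer(scr, "SCR"), a, b, c, d, chi2, p)


def intersect_gene_lists(list_a: set[str], list_b: set[str]
                         ) -> tuple[set[str], set[str], set[str]]:
    """Partition two gene sets into (common, a_only, b_only)."""
    a, b = set(list_a), set(list_b)
    return a & b, a - b, b - a
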