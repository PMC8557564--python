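"""Gene-set over-representation by Fisher's exact test.

Significant-gene lists (genes with >= 1 significant isoform, or >= 1
significant exon bin) are tested against the expressed-gene background with
the one-sided cumulative hypergeometric tail, one term at a time; term
members are intersected with the background first. Raw p-values are
reported (no multiplicity correction). GMT is the gene-set input format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["GeneSet", "EnrichmentResult", "read_gmt", "fisher_enrichment",
           "results_frame"]


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]
    source: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} has no members")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_total: int  # term genes in background
    n_sig: int  # significant genes in term
    p: float

    @property
    def pct_sig(self) -> float:
        return 100.0 * self.n_sig / self.n_total


def read_gmt(path: str, source: str = "custom") -> list[GeneSet]:
    """Parse GMT lines (term id, description, members...). Duplicate members
    are deduplicated with a warning; a line with < 3 fields is an error."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields, "
                    f"got {len(fields)}"
                )
            term_id, term_name, *members = fields
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate members in {term_id}"
                )
            sets.append(GeneSet(term_id, term_name, frozenset(members), source))
    return sets


def fisher_enrichment(
    sig_genes: set[str],
    background: set[str],
    sets: list[GeneSet],
    min_overlap: int = 1,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """One-sided over-representation p-value per term.

    With N = |background|, K = |term ∩ background|, n = |sig|,
    k = |sig ∩ term|: p = P[X >= k], X ~ Hypergeometric(N, K, n).
    Terms with k < ``min_overlap`` or K = 0 are skipped. Significant genes
    must be a subset of the background.
    """
    sig = set(sig_genes)
    bg = set(background)
    if not sig <= bg:
        missing = sorted(sig - bg)[:5]
        raise ValueError(f"significant genes absent from background: {missing}")
    N, n = len(bg), len(sig)
    out: list[EnrichmentResult] = []
    for gs in sets:
        term_bg = gs.members & bg
        K = len(term_bg)
        k = len(term_bg & sig)
        if K == 0 or k < min_overlap:
            continue
        if two_sided:
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        out.append(EnrichmentResult(gs.term_id, gs.term_name, K, k, min(p, 1.0)))
    return sorted(out, key=lambda r: r.p)


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "n_total": [r.n_total for r in results],
            "n_sig": [r.n_sig for r in results],
            "pct_sig": [r.pct_sig for r in results],
            "p_value": [r.p for r in results],
        }
    )
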