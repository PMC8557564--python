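"""Methylation-splicing integration.

The pipeline's bespoke downstream stage: every evaluated cytosine is
assigned to exactly one genomic category (exon > intron > promoter >
intergenic precedence, position-based, strand-ignored), each gene's region
classes get a methylation level — the ratio of differentially methylated
cytosines to all cytosines evaluated in the region — and the per-gene level
distributions of paired region classes are compared with two-sample
Kolmogorov-Smirnov tests:

* among genes with >= 1 differentially used exon bin: significant vs
  non-significant exon bins, and introns contiguous (immediately flanking)
  to significant bins vs non-contiguous introns;
* among genes with >= 1 differentially expressed isoform: exon bins covered
  by a significant isoform vs the remaining bins;
* promoter levels of genes with vs without differential isoform expression,
  and with vs without differential exon usage.

The distributions entering the KS tests are pooled per-feature by default
(one level per exon bin / intron / promoter): individual features are
similar-sized regions, so the two samples are exchangeable under the null
of no methylation-splicing association. The per-gene aggregation (one
level per gene per class) is available behind a flag but is anticonservative
for the exon comparison: a single significant bin's level has a much
smaller denominator than the pooled remaining bins, and the resulting
zero-inflation difference is itself a distribution-shape difference that
KS detects absent any methylation signal. Per-gene levels are always
reported in the region-level table either way. Genes without methylation
data in a class are excluded from that class's distribution and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import FlattenedGene, GeneModel
from .exon_usage import ExonUsageResult
from .isoform import FeatureTestResult

__all__ = [
    "FeatureAssignment",
    "RegionMethylation",
    "KSComparison",
    "assign_cytosines",
    "region_methylation",
    "classify_deu_regions",
    "classify_die_regions",
    "ks_compare",
    "run_integration",
    "gene_report",
    "annotate_dm",
    "cpg_count_tables",
]

CATEGORY_PRECEDENCE = ("exon", "intron", "promoter", "intergenic")


@dataclass(frozen=True)
class FeatureAssignment:
    chrom: str
    pos: int
    strand: str
    category: str  # exon | intron | promoter | intergenic
    gene_id: str = ""
    feature_id: str = ""  # bin or intron id, empty otherwise


@dataclass
class RegionMethylation:
    gene_id: str
    region_class: str
    n_eval: int
    n_dm: int

    @property
    def level(self) -> float | None:
        """DM-cytosine / evaluated-cytosine ratio; None when undefined."""
        if self.n_eval == 0:
            return None
        return self.n_dm / self.n_eval


@dataclass
class KSComparison:
    class_a: str
    class_b: str
    n_a: int
    n_b: int
    D: float
    p: float


def _build_trees(flat_genes: dict[str, FlattenedGene]):
    trees = {cat: {} for cat in ("exon", "intron", "promoter")}

    def add(cat: str, chrom: str, start: int, end: int, payload):
        trees[cat].setdefault(chrom, IntervalTree()).addi(start, end + 1, payload)

    for gid, fl in flat_genes.items():
        for bid, iv in fl.bins:
            add("exon", fl.chrom, iv.start, iv.end, (gid, bid))
        for intron in fl.introns:
            add("intron", fl.chrom, intron.interval.start, intron.interval.end,
                (gid, intron.intron_id))
        if fl.promoter is not None:
            add("promoter", fl.chrom, fl.promoter.start, fl.promoter.end, (gid, ""))
    return trees


def assign_cytosines(
    cytosine_keys: pd.DataFrame,
    flat_genes: dict[str, FlattenedGene],
) -> list[FeatureAssignment]:
    """Assign each (chrom, pos, strand) row to exactly one category.

    Precedence exon > intron > promoter > intergenic; within a category,
    ties across overlapping genes break deterministically to the lowest
    (gene_id, feature_id). Cytosine strand is ignored for assignment.
    """
    trees = _build_trees(flat_genes)
    out: list[FeatureAssignment] = []
    for row in cytosine_keys.itertuples(index=False):
        chrom, pos, strand = row.chrom, int(row.pos), row.strand
        hit = None
        for cat in ("exon", "intron", "promoter"):
            tree = trees[cat].get(chrom)
            if tree is None:
                continue
            matches = tree[pos]
            if matches:
                gid, fid = min(m.data for m in matches)
                hit = FeatureAssignment(chrom, pos, strand, cat, gid, fid)
                break
        if hit is None:
            hit = FeatureAssignment(chrom, pos, strand, "intergenic")
        out.append(hit)
    return out


def region_methylation(
    assignments: list[FeatureAssignment],
    dm: pd.DataFrame,
    gene_id: str,
    region_class: str,
    member: "callable",
) -> RegionMethylation:
    """Count evaluated and DM cytosines over the assignments selected by
    ``member`` (a predicate over FeatureAssignment)."""
    sig = _dm_lookup(dm)
    n_eval = 0
    n_dm = 0
    for a in assignments:
        if not member(a):
            continue
        n_eval += 1
        if sig.get((a.chrom, a.pos, a.strand), False):
            n_dm += 1
    return RegionMethylation(gene_id, region_class, n_eval, n_dm)


def _dm_lookup(dm: pd.DataFrame) -> dict:
    return {
        (c, int(p), s): bool(sg)
        for c, p, s, sg in zip(dm["chrom"], dm["pos"], dm["strand"], dm["significant"])
    }


def classify_deu_regions(
    gene: FlattenedGene, deu: list[ExonUsageResult]
) -> dict[str, set[str]]:
    """Partition a DEU gene's bins and introns by significance/contiguity.

    Returns {'sig_exons', 'nonsig_exons', 'contig_introns',
    'noncontig_introns'} mapping to feature-id sets. Contiguous introns are
    those immediately flanking (sharing a boundary with) any significant
    bin. Raises if the gene has no usage results or no significant bin.
    """
    mine = [r for r in deu if r.gene_id == gene.gene_id]
    if not mine:
        raise ValueError(f"gene {gene.gene_id} absent from exon-usage results")
    sig_bins = {r.bin_id for r in mine if r.significant}
    if not sig_bins:
        raise ValueError(f"gene {gene.gene_id} has no significant bin")
    all_bins = {bid for bid, _ in gene.bins}
    contig = {
        i.intron_id
        for i in gene.introns
        if i.upstream_bin in sig_bins or i.downstream_bin in sig_bins
    }
    return {
        "sig_exons": sig_bins,
        "nonsig_exons": all_bins - sig_bins,
        "contig_introns": contig,
        "noncontig_introns": {i.intron_id for i in gene.introns} - contig,
    }


def classify_die_regions(
    gene: GeneModel,
    flat: FlattenedGene,
    die: list[FeatureTestResult],
) -> dict[str, set[str]]:
    """Partition a DIE gene's bins into exons covered by a significant
    isoform vs the rest (interval overlap with the isoform's exons)."""
    sig_tids = {
        r.feature_id for r in die if r.gene_id == gene.gene_id and r.significant
    }
    die_bins: set[str] = set()
    for tid in sig_tids:
        for e in gene.transcripts.get(tid, []):
            for bid, iv in flat.bins:
                if iv.start <= e.end and e.start <= iv.end:
                    die_bins.add(bid)
    all_bins = {bid for bid, _ in flat.bins}
    return {"die_exons": die_bins, "nondie_exons": all_bins - die_bins}


def ks_compare(
    levels_a: np.ndarray | list[float],
    levels_b: np.ndarray | list[float],
    class_a: str = "a",
    class_b: str = "b",
    exact_limit: int = 10_000,
) -> KSComparison:
    """Two-sided two-sample KS test on per-gene methylation levels.

    Exact p-value when n_a * n_b <= ``exact_limit``, asymptotic otherwise.
    """
    a = np.asarray([x for x in levels_a if x is not None], dtype=float)
    b = np.asarray([x for x in levels_b if x is not None], dtype=float)
    if a.size == 0 or b.size == 0:
        empty = class_a if a.size == 0 else class_b
        raise ValueError(f"no defined methylation levels in class {empty!r}")
    method = "exact" if a.size * b.size <= exact_limit else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return KSComparison(class_a, class_b, int(a.size), int(b.size),
                        float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class IntegrationReport:
    comparisons: list[KSComparison]
    region_levels: pd.DataFrame  # gene_id, region_class, n_eval, n_dm, level
    n_deu_genes: int
    n_deu_genes_with_meth: int
    n_die_genes: int
    n_die_genes_with_meth: int

    def comparison(self, class_a: str, class_b: str) -> KSComparison:
        for c in self.comparisons:
            if (c.class_a, c.class_b) == (class_a, class_b):
                return c
        raise KeyError((class_a, class_b))

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class_a": c.class_a, "class_b": c.class_b,
                    "n_a": c.n_a, "n_b": c.n_b, "D": c.D, "p_value": c.p,
                }
                for c in self.comparisons
            ]
        )


def _counts_by_feature(assignments, dm):
    """(category, gene, feature) -> [n_eval, n_dm], plus promoter per gene."""
    sig = _dm_lookup(dm)
    counts: dict[tuple[str, str, str], list[int]] = {}
    for a in assignments:
        key = (a.category, a.gene_id, a.feature_id)
        c = counts.setdefault(key, [0, 0])
        c[0] += 1
        if sig.get((a.chrom, a.pos, a.strand), False):
            c[1] += 1
    return counts


def _index_counts(counts) -> dict:
    """Re-key per-feature counts as (category, gene) -> {feature_id: (ne, nd)}."""
    out: dict[tuple[str, str], dict[str, tuple[int, int]]] = {}
    for (cat, gid, fid), (ne, nd) in counts.items():
        out.setdefault((cat, gid), {})[fid] = (ne, nd)
    return out


def _level_of(indexed, category: str, gene_id: str, feature_ids: set[str] | None):
    n_eval = n_dm = 0
    for fid, (ne, nd) in indexed.get((category, gene_id), {}).items():
        if feature_ids is not None and fid not in feature_ids:
            continue
        n_eval += ne
        n_dm += nd
    return n_eval, n_dm


def run_integration(
    deu: list[ExonUsageResult],
    die: list[FeatureTestResult],
    dm: pd.DataFrame,
    genes: dict[str, GeneModel],
    flat_genes: dict[str, FlattenedGene],
    alpha_ks: float = 0.001,
    pooled: bool = True,
) -> IntegrationReport:
    """Compute region methylation levels and the five headline KS
    comparisons. ``pooled=True`` (default) enters one level per feature
    into the KS distributions; ``pooled=False`` aggregates to one level
    per gene per class (see module docstring for the caveat)."""
    assignments = assign_cytosines(dm[["chrom", "pos", "strand"]], flat_genes)
    counts = _index_counts(_counts_by_feature(assignments, dm))

    deu_genes = sorted({r.gene_id for r in deu if r.significant})
    die_genes = sorted({r.gene_id for r in die if r.significant})
    all_tested_deu = sorted({r.gene_id for r in deu})
    all_tested_die = sorted({r.gene_id for r in die})

    rows: list[dict] = []
    dists: dict[str, list[float]] = {
        k: []
        for k in (
            "sig_exons", "nonsig_exons", "contig_introns", "noncontig_introns",
            "die_exons", "nondie_exons", "promoter_deu", "promoter_nondeu",
            "promoter_die", "promoter_nondie",
        )
    }

    def record(gene_id: str, region_class: str, category: str,
               feature_ids: set[str] | None, dist_key: str | None):
        n_eval, n_dm = _level_of(counts, category, gene_id, feature_ids)
        rows.append(
            {
                "gene_id": gene_id,
                "region_class": region_class,
                "n_eval": n_eval,
                "n_dm": n_dm,
                "level": (n_dm / n_eval) if n_eval else np.nan,
            }
        )
        if dist_key is not None and n_eval:
            if pooled and feature_ids is not None:
                for fid in feature_ids:
                    ne, nd = _level_of(counts, category, gene_id, {fid})
                    if ne:
                        dists[dist_key].append(nd / ne)
            else:
                dists[dist_key].append(n_dm / n_eval)
        return n_eval

    n_deu_meth = 0
    for gid in deu_genes:
        parts = classify_deu_regions(flat_genes[gid], deu)
        got = 0
        got += record(gid, "sig_exons", "exon", parts["sig_exons"], "sig_exons")
        got += record(gid, "nonsig_exons", "exon", parts["nonsig_exons"], "nonsig_exons")
        got += record(gid, "contig_introns", "intron", parts["contig_introns"],
                      "contig_introns")
        got += record(gid, "noncontig_introns", "intron", parts["noncontig_introns"],
                      "noncontig_introns")
        if got:
            n_deu_meth += 1

    n_die_meth = 0
    for gid in die_genes:
        parts = classify_die_regions(genes[gid], flat_genes[gid], die)
        got = 0
        got += record(gid, "die_exons", "exon", parts["die_exons"], "die_exons")
        got += record(gid, "nondie_exons", "exon", parts["nondie_exons"], "nondie_exons")
        if got:
            n_die_meth += 1

    for gid in all_tested_die:
        key = "promoter_die" if gid in set(die_genes) else "promoter_nondie"
        record(gid, key, "promoter", None, key)
    for gid in all_tested_deu:
        key = "promoter_deu" if gid in set(deu_genes) else "promoter_nondeu"
        record(gid, key, "promoter", None, key)

    comparisons = []
    for a, b in (
        ("sig_exons", "nonsig_exons"),
        ("contig_introns", "noncontig_introns"),
        ("die_exons", "nondie_exons"),
        ("promoter_die", "promoter_nondie"),
        ("promoter_deu", "promoter_nondeu"),
    ):
        try:
            comparisons.append(ks_compare(dists[a], dists[b], a, b))
        except ValueError:
            comparisons.append(KSComparison(a, b, len(dists[a]), len(dists[b]),
                                            float("nan"), float("nan")))

    return IntegrationReport(
        comparisons=comparisons,
        region_levels=pd.DataFrame(rows),
        n_deu_genes=len(deu_genes),
        n_deu_genes_with_meth=n_deu_meth,
        n_die_genes=len(die_genes),
        n_die_genes_with_meth=n_die_meth,
    )


def annotate_dm(dm: pd.DataFrame, flat_genes: dict[str, FlattenedGene]) -> pd.DataFrame:
    """DM results with the assigned genomic region appended (category,
    gene id, feature id) — the per-cytosine report format."""
    assigns = assign_cytosines(dm[["chrom", "pos", "strand"]], flat_genes)
    out = dm.copy().reset_index(drop=True)
    out["category"] = [a.category for a in assigns]
    out["gene_id"] = [a.gene_id for a in assigns]
    out["feature_id"] = [a.feature_id for a in assigns]
    return out


def cpg_count_tables(
    dm: pd.DataFrame,
    genes: dict[str, GeneModel],
    flat_genes: dict[str, FlattenedGene],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluated/DM CpG counts (i) per transcript and (ii) per exon bin,
    intron and promoter.

    The per-transcript table counts cytosines falling in the transcript's
    own exons plus the gene promoter; the per-feature table is the
    assignment-based count for every flattened feature."""
    ann = annotate_dm(dm, flat_genes)
    feat = (
        ann[ann.category != "intergenic"]
        .groupby(["gene_id", "category", "feature_id"])
        .agg(n_eval=("significant", "size"), n_dm=("significant", "sum"))
        .reset_index()
    )
    pos_by_chrom: dict[str, np.ndarray] = {}
    sig_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in ann.groupby("chrom"):
        pos_by_chrom[chrom] = sub["pos"].to_numpy()
        sig_by_chrom[chrom] = sub["significant"].to_numpy(dtype=bool)

    def _count(chrom: str, intervals) -> tuple[int, int]:
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            return 0, 0
        mask = np.zeros(len(pos), dtype=bool)
        for iv in intervals:
            mask |= (pos >= iv.start) & (pos <= iv.end)
        return int(mask.sum()), int((mask & sig_by_chrom[chrom]).sum())

    rows = []
    for gid, g in genes.items():
        prom = flat_genes[gid].promoter
        for tid, exons in g.transcripts.items():
            ne, nd = _count(g.chrom, exons)
            pe, pdm = _count(g.chrom, [prom]) if prom is not None else (0, 0)
            rows.append(
                {
                    "transcript_id": tid, "gene_id": gid,
                    "n_eval_exons": ne, "n_dm_exons": nd,
                    "n_eval_promoter": pe, "n_dm_promoter": pdm,
                }
            )
    return pd.DataFrame(rows), feat


def gene_report(
    gene_id: str,
    bin_counts: pd.DataFrame,
    design,
    deu: list[ExonUsageResult],
    flat: FlattenedGene,
    dm: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene report: normalized mean bin expression per condition 5'->3'
    plus the gene's four DEU region-class methylation levels.

    Returns (expression table, methylation-level table)."""
    from . import nbglm

    sub = bin_counts[bin_counts["gene_id"] == gene_id]
    if sub.empty:
        raise KeyError(f"gene {gene_id} not in bin counts")
    sample_cols = list(design.sample_ids)
    full = bin_counts[sample_cols].to_numpy(dtype=float)
    factors = nbglm.size_factors(full, allow_pseudo_reference=True)
    norm = sub[sample_cols].to_numpy(dtype=float) / factors
    is_trt = design.indicator.astype(bool)
    sig_bins = {r.bin_id for r in deu if r.gene_id == gene_id and r.significant}
    order = [bid for bid, _ in flat.bins]
    expr = pd.DataFrame(
        {
            "bin_id": sub["bin_id"].to_numpy(),
            "mean_control": norm[:, ~is_trt].mean(axis=1),
            "mean_treatment": norm[:, is_trt].mean(axis=1),
            "significant": [b in sig_bins for b in sub["bin_id"]],
        }
    )
    expr["__o"] = expr["bin_id"].map({b: i for i, b in enumerate(order)})
    expr = expr.sort_values("__o").drop(columns="__o").reset_index(drop=True)

    assignments = assign_cytosines(dm[["chrom", "pos", "strand"]], {gene_id: flat})
    counts = _index_counts(_counts_by_feature(assignments, dm))
    parts = classify_deu_regions(flat, deu) if sig_bins else None
    rows = []
    classes = (
        ("sig_exons", "exon"), ("nonsig_exons", "exon"),
        ("contig_introns", "intron"), ("noncontig_introns", "intron"),
    )
    for cls, cat in classes:
        fids = parts[cls] if parts else (set() if "sig" in cls else None)
        n_eval, n_dm = _level_of(counts, cat, gene_id, fids)
        rows.append(
            {
                "region_class": cls,
                "n_eval": n_eval,
                "n_dm": n_dm,
                "level": (n_dm / n_eval) if n_eval else np.nan,
            }
        )
    return expr, pd.DataFrame(rows)
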