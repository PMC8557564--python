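"""Cytosine assignment, region levels, DEU/DIE region classes, KS tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from splicemeth import integration
from splicemeth.annotation import (
    GeneModel,
    GenomicInterval,
    flatten_gene,
)
from splicemeth.exon_usage import ExonUsageResult
from splicemeth.isoform import FeatureTestResult


def _gene(gene_id="G1", strand="+", exons=((1000, 1100), (1500, 1600), (2000, 2100), (2500, 2600))):
    tx = {f"{gene_id}.t1": [GenomicInterval("chr1", s, e, strand) for s, e in exons]}
    return GeneModel(gene_id, "chr1", strand, tx)


def keys(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


def test_assignment_categories_and_precedence():
    fl = flatten_gene(_gene())
    cyt = keys([
        ("chr1", 1550, "+"),   # inside bin E002
        ("chr1", 1200, "+"),   # intron I001
        ("chr1", 500, "+"),    # promoter (TSS=1000, window back to 1)
        ("chr1", 9000, "+"),   # intergenic
        ("chr2", 50, "+"),     # other chromosome -> intergenic
    ])
    res = integration.assign_cytosines(cyt, {"G1": fl})
    assert [(a.category, a.gene_id, a.feature_id) for a in res] == [
        ("exon", "G1", "E002"),
        ("intron", "G1", "I001"),
        ("promoter", "G1", ""),
        ("intergenic", "", ""),
        ("intergenic", "", ""),
    ]


def test_assignment_is_a_partition(small_dataset):
    flat = small_dataset["flat"]
    sites = small_dataset["meth"].sites[["chrom", "pos", "strand"]].head(400)
    res = integration.assign_cytosines(sites, flat)
    assert len(res) == len(sites)
    cats = pd.Series([a.category for a in res]).value_counts()
    assert cats.sum() == len(sites)
    assert set(cats.index) <= {"exon", "intron", "promoter", "intergenic"}


def test_region_methylation_counts_match_brute_force():
    rng = np.random.default_rng(0)
    fl = flatten_gene(_gene())
    pos = rng.integers(900, 2700, size=60)
    cyt = keys([("chr1", int(p), "+") for p in pos])
    dm = cyt.copy()
    dm["significant"] = rng.random(60) < 0.3
    assigns = integration.assign_cytosines(cyt, {"G1": fl})
    rm = integration.region_methylation(
        assigns, dm, "G1", "exons",
        lambda a: a.category == "exon" and a.gene_id == "G1",
    )
    # brute force: count positions in any bin interval
    in_exon = [
        any(iv.start <= p <= iv.end for _, iv in fl.bins) for p in pos
    ]
    assert rm.n_eval == sum(in_exon)
    assert rm.n_dm == sum(
        sig and ok for sig, ok in zip(dm["significant"], in_exon)
    )
    if rm.n_eval:
        assert rm.level == rm.n_dm / rm.n_eval


@pytest.mark.parametrize(
    "sig,contig,noncontig",
    [
        ({"E002"}, {"I001", "I002"}, {"I003"}),
        ({"E001"}, {"I001"}, {"I002", "I003"}),
        ({"E002", "E003"}, {"I001", "I002", "I003"}, set()),
    ],
)
def test_classify_deu_regions_adjacency(sig, contig, noncontig):
    fl = flatten_gene(_gene())
    deu = [
        ExonUsageResult("G1", bid, 1.0, 0.001 if bid in sig else 0.5, bid in sig)
        for bid, _ in fl.bins
    ]
    parts = integration.classify_deu_regions(fl, deu)
    assert parts["sig_exons"] == sig
    assert parts["contig_introns"] == contig
    assert parts["noncontig_introns"] == noncontig
    assert parts["nonsig_exons"] == {b for b, _ in fl.bins} - sig


def test_classify_deu_requires_results_and_significance():
    fl = flatten_gene(_gene())
    with pytest.raises(ValueError, match="absent"):
        integration.classify_deu_regions(fl, [])
    deu = [ExonUsageResult("G1", "E001", 0.0, 0.9, False)]
    with pytest.raises(ValueError, match="significant"):
        integration.classify_deu_regions(fl, deu)


def test_classify_die_regions_overlap_matches_per_base_oracle():
    g = _gene()
    g.transcripts["G1.t2"] = [
        GenomicInterval("chr1", 1000, 1100, "+"),
        GenomicInterval("chr1", 2000, 2100, "+"),
    ]
    fl = flatten_gene(g)
    die = [FeatureTestResult("G1.t2", "G1", 2.0, 0.001, True)]
    parts = integration.classify_die_regions(g, fl, die)
    # per-base oracle: a bin is a die-exon iff it shares a base with t2
    t2_bases = set(range(1000, 1101)) | set(range(2000, 2101))
    expect = {
        bid for bid, iv in fl.bins
        if set(range(iv.start, iv.end + 1)) & t2_bases
    }
    assert parts["die_exons"] == expect
    assert parts["nondie_exons"] == {b for b, _ in fl.bins} - expect


def test_classify_die_all_significant_empties_nondie():
    g = _gene()
    fl = flatten_gene(g)
    die = [FeatureTestResult("G1.t1", "G1", 2.0, 0.0001, True)]
    parts = integration.classify_die_regions(g, fl, die)
    assert parts["nondie_exons"] == set()


# ---------------------------------------------------------------------------
# KS


def test_ks_identical_samples():
    c = integration.ks_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    assert c.D == 0.0 and c.p == 1.0


def test_ks_disjoint_supports():
    c = integration.ks_compare([0.0, 0.1], [0.8, 0.9])
    assert c.D == 1.0


def test_ks_empty_sample_names_class():
    with pytest.raises(ValueError, match="empty_class"):
        integration.ks_compare([], [0.5], class_a="empty_class")


def test_ks_matches_exhaustive_permutation_oracle():
    rng = np.random.default_rng(1)
    a = rng.random(4)
    b = rng.random(4)
    c = integration.ks_compare(a, b)

    def ks_stat(x, y):
        allv = np.sort(np.concatenate([x, y]))
        fa = np.searchsorted(np.sort(x), allv, side="right") / len(x)
        fb = np.searchsorted(np.sort(y), allv, side="right") / len(y)
        return np.max(np.abs(fa - fb))

    pooled = np.concatenate([a, b])
    d_obs = ks_stat(a, b)
    count = total = 0
    for idx in combinations(range(8), 4):
        mask = np.zeros(8, bool)
        mask[list(idx)] = True
        d = ks_stat(pooled[mask], pooled[~mask])
        total += 1
        if d >= d_obs - 1e-12:
            count += 1
    assert c.p == pytest.approx(count / total, abs=1e-12)


def test_ks_symmetry():
    rng = np.random.default_rng(2)
    a, b = rng.random(6), rng.random(9)
    c1 = integration.ks_compare(a, b, "x", "y")
    c2 = integration.ks_compare(b, a, "y", "x")
    assert c1.D == c2.D and c1.p == c2.p


# ---------------------------------------------------------------------------
# end-to-end structure


def _tiny_integration(small_dataset, rna_design):
    from splicemeth import exon_usage, isoform, methylation

    deu = exon_usage.test_exon_usage(
        exon_usage.filter_genes(small_dataset["bins"]), rna_design
    )
    die = isoform.test_isoforms(
        isoform.filter_expressed(small_dataset["iso"]), rna_design
    )
    dm = methylation.test_dm(methylation.filter_cytosines(small_dataset["meth"]))
    return deu, die, dm


def test_run_integration_structure(small_dataset, rna_design):
    deu, die, dm = _tiny_integration(small_dataset, rna_design)
    rep = integration.run_integration(
        deu, die, dm, small_dataset["genes"], small_dataset["flat"]
    )
    assert [(c.class_a, c.class_b) for c in rep.comparisons] == [
        ("sig_exons", "nonsig_exons"),
        ("contig_introns", "noncontig_introns"),
        ("die_exons", "nondie_exons"),
        ("promoter_die", "promoter_nondie"),
        ("promoter_deu", "promoter_nondeu"),
    ]
    lv = rep.region_levels
    assert ((lv["n_dm"] <= lv["n_eval"])).all()
    defined = lv["level"].dropna()
    assert ((defined >= 0) & (defined <= 1)).all()
    # within a DEU gene the exon classes partition the exon-assigned cytosines
    for gid in {r.gene_id for r in deu if r.significant}:
        sub = lv[(lv.gene_id == gid)]
        n_sig = sub[sub.region_class == "sig_exons"]["n_eval"].sum()
        n_non = sub[sub.region_class == "nonsig_exons"]["n_eval"].sum()
        assigns = integration.assign_cytosines(
            dm[["chrom", "pos", "strand"]], {gid: small_dataset["flat"][gid]}
        )
        n_exon = sum(a.category == "exon" for a in assigns)
        assert n_sig + n_non == n_exon
    assert rep.n_deu_genes_with_meth <= rep.n_deu_genes
    assert rep.n_die_genes_with_meth <= rep.n_die_genes


def test_gene_report_shapes(small_dataset, rna_design):
    deu, die, dm = _tiny_integration(small_dataset, rna_design)
    sig_genes = [r.gene_id for r in deu if r.significant]
    if not sig_genes:
        pytest.skip("no significant usage gene in this fixture")
    gid = sig_genes[0]
    expr, levels = integration.gene_report(
        gid, small_dataset["bins"], rna_design, deu,
        small_dataset["flat"][gid], dm,
    )
    n_bins = len(small_dataset["flat"][gid].bins)
    assert len(expr) == n_bins
    assert list(levels["region_class"]) == [
        "sig_exons", "nonsig_exons", "contig_introns", "noncontig_introns",
    ]
    # expression rows match brute-force normalized means
    from splicemeth import nbglm

    sample_cols = list(rna_design.sample_ids)
    full = small_dataset["bins"][sample_cols].to_numpy(float)
    f = nbglm.size_factors(full, allow_pseudo_reference=True)
    sub = small_dataset["bins"][small_dataset["bins"].gene_id == gid]
    row0 = sub.iloc[0]
    ctrl_cols = [s for s, c in zip(rna_design.sample_ids, rna_design.condition)
                 if c == "control"]
    idx = [sample_cols.index(s) for s in ctrl_cols]
    manual = np.mean([row0[s] / f[sample_cols.index(s)] for s in ctrl_cols])
    got = expr.loc[expr.bin_id == row0["bin_id"], "mean_control"].iloc[0]
    assert got == pytest.approx(manual)


def test_annotate_dm_and_cpg_count_tables(small_dataset, rna_design):
    deu, die, dm = _tiny_integration(small_dataset, rna_design)
    flat = small_dataset["flat"]
    ann = integration.annotate_dm(dm, flat)
    assert len(ann) == len(dm)
    assert set(ann.category.unique()) <= {"exon", "intron", "promoter", "intergenic"}
    per_tx, per_feat = integration.cpg_count_tables(dm, small_dataset["genes"], flat)
    n_tx = sum(len(g.transcripts) for g in small_dataset["genes"].values())
    assert len(per_tx) == n_tx
    assert (per_feat["n_dm"] <= per_feat["n_eval"]).all()
    # feature-level evaluated counts sum to the non-intergenic assignments
    assert per_feat["n_eval"].sum() == (ann.category != "intergenic").sum()


def test_gene_report_unknown_gene():
    with pytest.raises(KeyError):
        integration.gene_report(
            "NOPE",
            pd.DataFrame({"gene_id": [], "bin_id": []}),
            None, [], None, pd.DataFrame(),
        )
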