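"""Synthetic two-condition muscle-study data with planted effects.

Emulates the statistical structure of a maternal-diet design: NB-distributed
isoform and exon-bin counts for 9 control vs 10 treatment RNA samples, and
binomial bisulfite methylation calls for 7 vs 9 samples, with

* planted differentially expressed isoforms (treatment mean multiplied by
  ``2**die_log2fc``),
* planted differentially used exon bins (one bin per selected gene; its
  share of the gene's expression multiplied by ``deu_usage_shift`` in
  treatment, shares renormalized within the gene),
* planted differentially methylated CpG sites, with a tunable coupling that
  enriches DM sites inside differentially used bins and their two flanking
  introns.

Randomness is split into independent substreams (annotation, counts,
methylome) spawned from one seed, so e.g. changing ``cpg_density`` leaves
the count matrices untouched. All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import FlattenedGene, GeneModel, GenomicInterval, flatten_gene

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "MethylationData",
    "generate_annotation",
    "generate_counts",
    "generate_methylome",
    "simulate_all",
]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generator parameters. Defaults are the emulated study's conditions.

    Sample sizes mirror the study design (9 control vs 10 treatment RNA
    samples; 7 vs 9 for methylation). Effect sizes default to the planted
    magnitudes used throughout the test suite: isoform log2 fold-change 2,
    usage-share shift x4, methylation-difference delta 0.30 on a 4 %
    background DM rate with a 5-fold coupling into differentially used bins
    and their flanking introns.
    """

    seed: int = 0
    n_genes: int = 300
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (3, 9)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 1500)
    intergenic_gap: tuple[int, int] = (7000, 12000)
    # RNA design
    n_control: int = 9
    n_treatment: int = 10
    # methylation design
    n_control_meth: int = 7
    n_treatment_meth: int = 9
    # expression / library model
    library_size_mean: float = 1.0
    library_size_spread: float = 0.2  # lognormal sigma of per-sample depth
    isoform_log_mean: float = float(np.log(150.0))
    isoform_log_sd: float = 1.0
    dispersion_log_mean: float = float(np.log(0.1))
    dispersion_log_sd: float = 0.3
    # planted expression/usage effects
    die_fraction: float = 0.1
    die_log2fc: float = 2.0
    deu_fraction: float = 0.3
    deu_usage_shift: float = 4.0
    # baseline usage share given to the planted bin (a minor alternative
    # exon) before the treatment shift is applied; keeps the renormalization
    # side-effect on sibling bins small
    deu_base_share: float = 0.03
    # methylome
    # expected CpG sites per 100 bp; genic regions are CpG-dense relative to
    # the genome-wide average (~1/100 bp including CpG deserts)
    cpg_density: float = 2.0
    coverage_mean: float = 20.0
    baseline_meth_shapes: tuple[tuple[float, float], ...] = ((8.0, 2.0), (2.0, 8.0))
    baseline_meth_weights: tuple[float, ...] = (0.6, 0.4)
    dm_fraction_background: float = 0.04
    dm_delta: float = 0.3
    coupling_enrichment: float = 5.0
    promoter_window: int = 3000

    def validate(self) -> None:
        for name in ("die_fraction", "deu_fraction", "dm_fraction_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_control", "n_treatment", "n_control_meth", "n_treatment_meth"
        ):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")
        if self.coupling_enrichment < 1.0:
            raise ConfigError("coupling_enrichment must be >= 1")
        for name in (
            "transcripts_per_gene", "exons_per_transcript",
            "exon_length", "intron_length", "intergenic_gap",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"infeasible range {name}={lo, hi}")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0.0 <= self.dm_delta <= 1.0:
            raise ConfigError("dm_delta outside [0, 1]")

    def streams(self) -> tuple[np.random.Generator, ...]:
        """Independent substreams: (annotation, counts, methylome)."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


@dataclass
class GroundTruth:
    """Planted effects, keyed by generated feature ids."""

    die_isoforms: dict[str, float] = field(default_factory=dict)  # tid -> log2fc
    deu_bins: dict[tuple[str, str], float] = field(default_factory=dict)
    dm_sites: dict[tuple[str, int], float] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "die": pd.DataFrame(
                [(t, f) for t, f in sorted(self.die_isoforms.items())],
                columns=["transcript_id", "true_log2fc"],
            ),
            "deu": pd.DataFrame(
                [(g, b, s) for (g, b), s in sorted(self.deu_bins.items())],
                columns=["gene_id", "bin_id", "true_shift"],
            ),
            "dm": pd.DataFrame(
                [(c, p, d) for (c, p), d in sorted(self.dm_sites.items())],
                columns=["chrom", "pos", "true_delta"],
            ),
        }


def _randint(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(cfg: SimulationConfig) -> dict[str, GeneModel]:
    """Non-overlapping genes on a synthetic chromosome, deterministic in seed.

    Each gene has a skeleton of exons separated by introns; the first
    transcript always carries the full skeleton, additional transcripts drop
    internal skeleton exons at random. Flattened counting bins therefore
    coincide with skeleton exons, which keeps planted usage effects
    identifiable per bin.
    """
    cfg.validate()
    rng, _, _ = cfg.streams()
    genes: dict[str, GeneModel] = {}
    chrom = "chr1"
    cursor = 10_000
    for i in range(cfg.n_genes):
        gid = f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = _randint(rng, cfg.exons_per_transcript)
        exons: list[GenomicInterval] = []
        pos = cursor
        for k in range(n_ex):
            length = _randint(rng, cfg.exon_length)
            exons.append(GenomicInterval(chrom, pos, pos + length - 1, strand))
            pos += length
            if k < n_ex - 1:
                pos += _randint(rng, cfg.intron_length)
        n_tx = _randint(rng, cfg.transcripts_per_gene)
        transcripts: dict[str, list[GenomicInterval]] = {f"{gid}.t1": list(exons)}
        for j in range(2, n_tx + 1):
            kept = [exons[0]]
            for e in exons[1:-1]:
                if rng.random() >= 0.3:
                    kept.append(e)
            if n_ex > 1:
                kept.append(exons[-1])
            transcripts[f"{gid}.t{j}"] = kept
        genes[gid] = GeneModel(gid, chrom, strand, transcripts, gene_name=f"SYN{i + 1}")
        cursor = pos + _randint(rng, cfg.intergenic_gap)
    return genes


# ---------------------------------------------------------------------------
# counts


def _sample_ids(n_ctrl: int, n_trt: int, prefix: str = "") -> tuple[list[str], list[str]]:
    ids = [f"{prefix}C{j + 1:02d}" for j in range(n_ctrl)] + [
        f"{prefix}T{j + 1:02d}" for j in range(n_trt)
    ]
    cond = ["control"] * n_ctrl + ["treatment"] * n_trt
    return ids, cond


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson NB2 sampling, robust for tiny dispersions."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    lam = np.where(
        alpha > 1e-6,
        rng.gamma(np.clip(1.0 / np.maximum(alpha, 1e-12), None, 1e12),
                  np.maximum(alpha, 1e-12) * mu),
        mu,
    )
    return rng.poisson(lam)


def generate_counts(
    cfg: SimulationConfig, genes: dict[str, GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Isoform and exon-bin count matrices with planted DIE/DEU effects.

    Returns (isoform counts, bin counts, sample design, ground truth).
    The isoform table is indexed by transcript_id with a leading ``gene_id``
    column; the bin table has leading ``gene_id``/``bin_id`` columns. Sample
    columns follow in design order.
    """
    cfg.validate()
    _, rng, _ = cfg.streams()
    sample_ids, cond = _sample_ids(cfg.n_control, cfg.n_treatment)
    n = len(sample_ids)
    is_trt = np.array([c == "treatment" for c in cond])
    depth = cfg.library_size_mean * rng.lognormal(
        -0.5 * cfg.library_size_spread**2, cfg.library_size_spread, size=n
    )

    flat = {gid: flatten_gene(g, cfg.promoter_window) for gid, g in genes.items()}
    iso_index = [(gid, tid) for gid, g in sorted(genes.items()) for tid in g.transcripts]
    n_iso = len(iso_index)

    expr = rng.lognormal(cfg.isoform_log_mean, cfg.isoform_log_sd, size=n_iso)
    disp_iso = rng.lognormal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, size=n_iso)

    truth = GroundTruth()
    n_die = round(cfg.die_fraction * n_iso)
    if n_die:
        for idx in rng.choice(n_iso, size=n_die, replace=False):
            truth.die_isoforms[iso_index[idx][1]] = cfg.die_log2fc

    # isoform means: expression x per-sample depth, x 2^lfc in treatment for DIE
    mu = expr[:, None] * depth[None, :]
    for i, (_gid, tid) in enumerate(iso_index):
        if tid in truth.die_isoforms:
            mu[i, is_trt] *= 2.0 ** truth.die_isoforms[tid]
    iso_counts = _nb_draw(rng, mu, disp_iso[:, None])

    # planted DEU genes: one bin per selected gene, chosen among genes with >= 2 bins
    eligible = [gid for gid in sorted(genes) if len(flat[gid].bins) >= 2]
    n_deu = min(round(cfg.deu_fraction * cfg.n_genes), len(eligible))
    if n_deu:
        for gi in rng.choice(len(eligible), size=n_deu, replace=False):
            gid = eligible[gi]
            bins = flat[gid].bins
            bid = bins[int(rng.integers(len(bins)))][0]
            truth.deu_bins[(gid, bid)] = cfg.deu_usage_shift

    # bin means: distribute each transcript's mean over its bins by length
    iso_pos = {key: i for i, key in enumerate(iso_index)}
    bin_rows: list[tuple[str, str]] = []
    bin_mu_rows: list[np.ndarray] = []
    for gid, g in sorted(genes.items()):
        fl = flat[gid]
        key_of = {(iv.start, iv.end): bid for bid, iv in fl.bins}
        bin_ids = [bid for bid, _ in fl.bins]
        m = np.zeros((len(bin_ids), n))
        order = {bid: k for k, bid in enumerate(bin_ids)}
        for tid, exons in g.transcripts.items():
            i = iso_pos[(gid, tid)]
            t_len = sum(len(e) for e in exons)
            for e in exons:
                bid = key_of[(e.start, e.end)]
                m[order[bid]] += mu[i] * (len(e) / t_len)
        for (pg, pb), shift in truth.deu_bins.items():
            if pg != gid:
                continue
            k = order[pb]
            tot = m.sum(axis=0)
            w = np.where(tot > 0, m / np.where(tot > 0, tot, 1.0), 0.0)
            # rebase the planted bin to a minor usage share in both
            # conditions, scaling siblings up proportionally
            base = cfg.deu_base_share
            others = 1.0 - w[k]
            scale = np.where(others > 0, (1.0 - base) / np.where(others > 0, others, 1.0), 1.0)
            w *= scale
            w[k] = base
            # treatment-only usage shift, shares renormalized within gene
            w[k, is_trt] *= shift
            colsum = w.sum(axis=0)
            w = w / np.where(colsum > 0, colsum, 1.0)
            m = w * tot
        bin_rows.extend((gid, bid) for bid in bin_ids)
        bin_mu_rows.append(m)
    bin_mu = np.vstack(bin_mu_rows)
    disp_bin = rng.lognormal(cfg.dispersion_log_mean, cfg.dispersion_log_sd,
                             size=bin_mu.shape[0])
    bin_counts = _nb_draw(rng, bin_mu, disp_bin[:, None])

    iso_df = pd.DataFrame(iso_counts, columns=sample_ids)
    iso_df.insert(0, "gene_id", [g for g, _ in iso_index])
    iso_df.index = pd.Index([t for _, t in iso_index], name="transcript_id")
    bin_df = pd.DataFrame(bin_counts, columns=sample_ids)
    bin_df.insert(0, "gene_id", [g for g, _ in bin_rows])
    bin_df.insert(1, "bin_id", [b for _, b in bin_rows])
    bin_df.index = pd.RangeIndex(len(bin_df))
    design = pd.DataFrame({"sample_id": sample_ids, "condition": cond})
    return iso_df, bin_df, design, truth


# ---------------------------------------------------------------------------
# methylome


@dataclass
class MethylationData:
    """Matrix container for per-site, per-sample bisulfite counts.

    ``sites`` has one row per (chrom, pos, strand, context) record; ``meth``
    and ``total`` are aligned (sites x samples) integer arrays.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    sample_ids: list[str]
    condition: list[str]

    def validate(self) -> None:
        if np.any(self.meth > self.total) or np.any(self.meth < 0):
            raise ValueError("need 0 <= meth <= total")
        if self.meth.shape != self.total.shape or self.meth.shape != (
            len(self.sites),
            len(self.sample_ids),
        ):
            raise ValueError("shape mismatch between sites and count arrays")


def _place_cpgs(
    rng: np.random.Generator, lo: int, hi: int, density_per_100bp: float
) -> np.ndarray:
    """CpG site positions (the + strand C) within [lo, hi], min spacing 2."""
    length = hi - lo + 1
    if length < 2:
        return np.empty(0, dtype=int)
    n = rng.poisson(length * density_per_100bp / 100.0)
    if n == 0:
        return np.empty(0, dtype=int)
    pos = np.sort(rng.choice(np.arange(lo, hi), size=min(n, max(1, (hi - lo) // 2)),
                             replace=False))
    keep = np.concatenate([[True], np.diff(pos) >= 2])
    return pos[keep]


def generate_methylome(
    cfg: SimulationConfig,
    genes: dict[str, GeneModel],
    truth: GroundTruth,
) -> tuple[MethylationData, pd.DataFrame]:
    """Binomial bisulfite counts over CpG sites placed in genes, promoters
    and intergenic gaps, with planted DM sites enriched in coupled regions.

    A "coupled" region is a planted differentially used bin or one of its
    two flanking introns; CpG sites there become DM with probability
    ``min(1, dm_fraction_background * coupling_enrichment)``, elsewhere with
    the background probability (both realized as exact deterministic counts
    per stratum). Each CpG site emits a + strand record at its position and
    a - strand record at position + 1, sharing the site's methylation state.

    Returns (MethylationData, methylation sample design).
    """
    cfg.validate()
    _, _, rng = cfg.streams()
    flat = {gid: flatten_gene(g, cfg.promoter_window) for gid, g in genes.items()}

    # coupled intervals: planted bins + flanking introns
    coupled: list[GenomicInterval] = []
    for (gid, bid), _shift in truth.deu_bins.items():
        fl = flat[gid]
        coupled.append(fl.bin_interval(bid))
        for intron in fl.introns:
            if bid in (intron.upstream_bin, intron.downstream_bin):
                coupled.append(intron.interval)

    # regions to seed with CpGs: gene spans, promoters, intergenic gaps
    regions: list[tuple[int, int]] = []
    spans = sorted(
        (genes[gid].span.start, genes[gid].span.end) for gid in genes
    )
    for gid in sorted(genes):
        sp = genes[gid].span
        regions.append((sp.start, sp.end))
        prom = flat[gid].promoter
        if prom is not None:
            regions.append((prom.start, prom.end))
    prev_end = 1
    for s, e in spans:
        if s - 1 >= prev_end:
            regions.append((prev_end, s - 1))
        prev_end = max(prev_end, e + 1)
    regions.sort()

    pos_list: list[np.ndarray] = []
    for lo, hi in regions:
        pos_list.append(_place_cpgs(rng, lo, hi, cfg.cpg_density))
    positions = np.unique(np.concatenate(pos_list)) if pos_list else np.empty(0, int)
    # enforce global spacing across region boundaries
    if positions.size:
        keep = np.concatenate([[True], np.diff(positions) >= 2])
        positions = positions[keep]
    n_sites = positions.size
    chrom = "chr1"

    in_coupled = np.zeros(n_sites, dtype=bool)
    for iv in coupled:
        in_coupled |= (positions >= iv.start) & (positions <= iv.end)

    # stratified exact DM counts
    p_coupled = min(1.0, cfg.dm_fraction_background * cfg.coupling_enrichment)
    is_dm = np.zeros(n_sites, dtype=bool)
    for stratum, p in ((in_coupled, p_coupled), (~in_coupled, cfg.dm_fraction_background)):
        idx = np.flatnonzero(stratum)
        k = round(p * idx.size)
        if k:
            is_dm[rng.choice(idx, size=k, replace=False)] = True

    comp = rng.choice(len(cfg.baseline_meth_weights), size=n_sites,
                      p=np.asarray(cfg.baseline_meth_weights))
    shapes = np.asarray(cfg.baseline_meth_shapes, dtype=float)
    baseline = rng.beta(shapes[comp, 0], shapes[comp, 1])
    # apply delta toward the side with headroom
    delta = np.where(baseline > 0.5, -cfg.dm_delta, cfg.dm_delta)
    p_trt_site = np.clip(baseline + np.where(is_dm, delta, 0.0), 0.0, 1.0)

    sample_ids, cond = _sample_ids(cfg.n_control_meth, cfg.n_treatment_meth, prefix="M")
    n_samp = len(sample_ids)
    is_trt = np.array([c == "treatment" for c in cond])
    p_mat = np.where(is_trt[None, :], p_trt_site[:, None], baseline[:, None])

    # two strand records per site, independent coverage, shared proportion
    rows = []
    meth_parts = []
    total_parts = []
    for strand, offset in (("+", 0), ("-", 1)):
        total = rng.poisson(cfg.coverage_mean, size=(n_sites, n_samp))
        meth = rng.binomial(total, p_mat)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": positions + offset,
                    "strand": strand,
                    "context": "CpG",
                    "site_pos": positions,
                }
            )
        )
        meth_parts.append(meth)
        total_parts.append(total)
    sites = pd.concat(rows, ignore_index=True)
    meth = np.vstack(meth_parts)
    total = np.vstack(total_parts)
    order = np.lexsort((sites["strand"].to_numpy(), sites["pos"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    meth = meth[order]
    total = total[order]

    truth.dm_sites.update(
        {(chrom, int(p)): float(d) for p, d, dm in
         zip(positions, delta, is_dm) if dm}
    )
    data = MethylationData(sites, meth, total, sample_ids, cond)
    data.validate()
    design = pd.DataFrame({"sample_id": sample_ids, "condition": cond})
    return data, design


def simulate_all(cfg: SimulationConfig):
    """Convenience wrapper: annotation, counts, methylome in one call."""
    genes = generate_annotation(cfg)
    iso, bins, design_rna, truth = generate_counts(cfg, genes)
    methylome, design_meth = generate_methylome(cfg, genes, truth)
    return genes, iso, bins, design_rna, design_meth, methylome, truth
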