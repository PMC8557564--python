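"""Per-cytosine differential methylation.

Consumes Bismark-style cytosine reports (one per sample; tab-separated
chrom, 1-based position, strand, methylated count, unmethylated count,
context, trinucleotide), merges them by (chrom, pos, strand), filters to
CpG-context cytosines with read coverage >= 8, and tests each retained
cytosine with an exact binomial-logistic likelihood-ratio test between
conditions. Each strand of a CpG is tested separately (an optional strand
merge collapses the palindrome). Under-covered samples are dropped
record-wise; a record is kept only while >= 2 samples per condition remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nbglm

__all__ = [
    "DMResult",
    "read_cytosine_report",
    "write_cytosine_report",
    "filter_cytosines",
    "merge_strands",
    "test_dm",
]

_CONTEXT_ALIASES = {"CG": "CpG", "CPG": "CpG", "CpG": "CpG", "CHG": "CHG", "CHH": "CHH"}


class CytosineReportError(ValueError):
    pass


@dataclass
class DMResult:
    chrom: str
    pos: int
    strand: str
    effect: float  # percentage-point methylation difference, treatment - control
    p: float
    significant: bool


def _normalize_context(raw: str, path: str, lineno: int) -> str:
    ctx = _CONTEXT_ALIASES.get(raw) or _CONTEXT_ALIASES.get(raw.upper())
    if ctx is None:
        raise CytosineReportError(f"{path}: line {lineno}: unknown context {raw!r}")
    return ctx


def read_cytosine_report(paths: dict[str, str], condition: dict[str, str]):
    """Merge per-sample cytosine reports into one matrix container.

    ``paths`` maps sample id -> report path; ``condition`` maps sample id ->
    condition label. Records are keyed by (chrom, pos, strand); a sample
    with no line for a key contributes total 0 there. Negative counts or an
    unknown strand raise a parse error naming the offending line.
    """
    from .simulate import MethylationData

    sample_ids = list(paths)
    per_sample: list[pd.DataFrame] = []
    for sid in sample_ids:
        path = paths[sid]
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 6:
                    raise CytosineReportError(
                        f"{path}: line {lineno}: expected >= 6 columns, got {len(f)}"
                    )
                chrom, pos, strand, n_meth, n_unmeth, ctx = f[:6]
                if strand not in ("+", "-"):
                    raise CytosineReportError(
                        f"{path}: line {lineno}: unknown strand {strand!r}"
                    )
                nm, nu = int(n_meth), int(n_unmeth)
                if nm < 0 or nu < 0:
                    raise CytosineReportError(
                        f"{path}: line {lineno}: negative count"
                    )
                rows.append(
                    (chrom, int(pos), strand,
                     _normalize_context(ctx, path, lineno), nm, nu)
                )
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"]
        )
        df = df.set_index(["chrom", "pos", "strand"])
        per_sample.append(df)

    keys = per_sample[0].index
    for df in per_sample[1:]:
        keys = keys.union(df.index)
    keys = keys.sort_values()
    n = len(keys)
    meth = np.zeros((n, len(sample_ids)), dtype=np.int64)
    total = np.zeros_like(meth)
    context = pd.Series("CpG", index=keys, dtype=object)
    for j, df in enumerate(per_sample):
        sub = df.reindex(keys)
        m = sub["meth"].fillna(0).to_numpy(dtype=np.int64)
        u = sub["unmeth"].fillna(0).to_numpy(dtype=np.int64)
        meth[:, j] = m
        total[:, j] = m + u
        has = sub["context"].notna()
        context[has] = sub.loc[has.to_numpy(), "context"]
    sites = keys.to_frame(index=False)
    sites["context"] = context.to_numpy()
    data = MethylationData(
        sites=sites,
        meth=meth,
        total=total,
        sample_ids=sample_ids,
        condition=[condition[s] for s in sample_ids],
    )
    data.validate()
    return data


def write_cytosine_report(data, sample_id: str, path: str) -> None:
    """Write one sample's records in Bismark cytosine-report column order."""
    j = data.sample_ids.index(sample_id)
    tri = {"CpG": "CGN", "CHG": "CAG", "CHH": "CTT"}
    with open(path, "w") as fh:
        for i, row in enumerate(data.sites.itertuples(index=False)):
            m = int(data.meth[i, j])
            u = int(data.total[i, j]) - m
            ctx = getattr(row, "context", "CpG")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{m}\t{u}\t{ctx}\t"
                f"{tri.get(ctx, 'NNN')}\n"
            )


def filter_cytosines(
    data,
    min_coverage: int = 8,
    context: str = "CpG",
    min_per_group: int = 2,
    require_all_samples: bool = False,
):
    """Coverage/context filter.

    Keeps records of the requested context; samples with total <
    ``min_coverage`` are dropped from a record (their counts zeroed), and
    the record survives only if >= ``min_per_group`` covered samples remain
    in each condition. With ``require_all_samples`` every sample must reach
    the coverage threshold instead. Idempotent by construction.
    """
    from .simulate import MethylationData

    is_trt = np.array([c != "control" for c in data.condition])
    ctx_col = data.sites["context"] if "context" in data.sites.columns else "CpG"
    ctx_ok = (
        (ctx_col == context).to_numpy()
        if isinstance(ctx_col, pd.Series)
        else np.ones(len(data.sites), dtype=bool)
    )
    covered = data.total >= min_coverage
    if require_all_samples:
        keep = ctx_ok & covered.all(axis=1)
    else:
        keep = (
            ctx_ok
            & (covered[:, ~is_trt].sum(axis=1) >= min_per_group)
            & (covered[:, is_trt].sum(axis=1) >= min_per_group)
        )
    meth = np.where(covered, data.meth, 0)[keep]
    total = np.where(covered, data.total, 0)[keep]
    out = MethylationData(
        sites=data.sites.loc[keep].reset_index(drop=True),
        meth=meth,
        total=total,
        sample_ids=list(data.sample_ids),
        condition=list(data.condition),
    )
    out.validate()
    return out


def merge_strands(data):
    """Collapse the CpG palindrome: a - strand record at pos p is pooled
    into the + strand record at p - 1 when present."""
    from .simulate import MethylationData

    sites = data.sites.copy().reset_index(drop=True)
    key = np.where(
        sites["strand"].to_numpy() == "-",
        sites["pos"].to_numpy() - 1,
        sites["pos"].to_numpy(),
    )
    sites["site_key"] = list(zip(sites["chrom"], key))
    order: dict[tuple, int] = {}
    for k in sites["site_key"]:
        order.setdefault(k, len(order))
    idx = np.array([order[k] for k in sites["site_key"]])
    n = len(order)
    meth = np.zeros((n, len(data.sample_ids)), dtype=np.int64)
    total = np.zeros_like(meth)
    np.add.at(meth, idx, data.meth)
    np.add.at(total, idx, data.total)
    first = sites.groupby("site_key", sort=False).head(1).copy()
    first["strand"] = "+"
    first["pos"] = [k[1] for k in first["site_key"]]
    first = first.drop(columns=["site_key"]).reset_index(drop=True)
    out = MethylationData(first, meth, total, list(data.sample_ids), list(data.condition))
    out.validate()
    return out


def test_dm(data, alpha: float = 0.01) -> pd.DataFrame:
    """Binomial-logistic LRT per retained cytosine.

    Returns a table with chrom/pos/strand, the methylation difference in
    percentage points (treatment - control), the nominal p-value and the
    significance flag at ``alpha``.
    """
    is_trt = np.array([c != "control" for c in data.condition])
    out = data.sites[["chrom", "pos", "strand"]].copy().reset_index(drop=True)
    if len(out) == 0:
        out["effect"] = out["p_value"] = []
        out["significant"] = []
        return out
    effect, _stat, p = nbglm.binomial_lrt_matrix(data.meth, data.total, is_trt)
    out["effect"] = effect
    out["p_value"] = p
    out["significant"] = np.isfinite(p) & (p <= alpha)
    return out
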