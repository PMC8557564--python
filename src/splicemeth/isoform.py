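"""Differential isoform expression.

Expression filtering (>= 2 counts in >= 9 replicates, group-agnostic),
median-of-ratios normalization, per-isoform NB dispersion estimation and
Wald tests of the condition coefficient, significance at a nominal p-value
threshold (default 0.01). Nominal p-values drive the significant flag; a
Benjamini-Hochberg column can be emitted for reference but is never used
for calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nbglm

__all__ = ["FeatureTestResult", "filter_expressed", "test_isoforms", "results_frame"]


@dataclass
class FeatureTestResult:
    feature_id: str
    gene_id: str
    log2fc: float
    p: float
    significant: bool
    gene_name: str | None = None
    converged: bool = True


def filter_expressed(
    counts: pd.DataFrame, min_count: int = 2, min_samples: int = 9
) -> pd.DataFrame:
    """Keep features with >= min_count reads in >= min_samples samples.

    The rule ignores group labels. Non-sample columns (``gene_id``,
    ``bin_id``, ``gene_name``) are preserved.
    """
    sample_cols = [c for c in counts.columns if c not in ("gene_id", "bin_id", "gene_name")]
    if min_samples > len(sample_cols):
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {len(sample_cols)}"
        )
    m = counts[sample_cols].to_numpy()
    keep = (m >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def test_isoforms(
    counts: pd.DataFrame,
    design: nbglm.DesignInfo,
    alpha: float = 0.01,
) -> list[FeatureTestResult]:
    """Per-isoform NB Wald tests of treatment vs control expression.

    ``counts`` must already be expression-filtered and carry a ``gene_id``
    column plus one column per design sample. Results keep input order and
    are one per feature; non-converged fits carry a NaN p-value and a
    cleared flag.
    """
    sample_cols = list(design.sample_ids)
    meta_gene = counts["gene_id"] if "gene_id" in counts.columns else None
    meta_name = counts["gene_name"] if "gene_name" in counts.columns else None
    m = counts[sample_cols].to_numpy(dtype=float)
    if m.shape[0] == 0:
        return []
    factors = nbglm.size_factors(m)
    X = design.model_matrix()
    offset = np.log(factors)
    results: list[FeatureTestResult] = []
    for i, fid in enumerate(counts.index):
        disp = nbglm.estimate_dispersion_single(m[i], X, offset)
        log2fc, _se, p, ok = nbglm.nb_wald(m[i], factors, design, disp)
        results.append(
            FeatureTestResult(
                feature_id=str(fid),
                gene_id=str(meta_gene.iloc[i]) if meta_gene is not None else "",
                gene_name=str(meta_name.iloc[i]) if meta_name is not None else None,
                log2fc=log2fc,
                p=p,
                significant=bool(np.isfinite(p) and p <= alpha),
                converged=ok,
            )
        )
    return results


def results_frame(results: list[FeatureTestResult], adjust: bool = False) -> pd.DataFrame:
    """Results as a table (transcript id, gene id, gene name, log2fc, p)."""
    df = pd.DataFrame(
        {
            "transcript_id": [r.feature_id for r in results],
            "gene_id": [r.gene_id for r in results],
            "gene_name": [r.gene_name for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p for r in results],
            "significant": [r.significant for r in results],
        }
    )
    if adjust and len(df):
        p = df["p_value"].to_numpy()
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if finite.any():
            adj[finite] = stats.false_discovery_control(p[finite], method="bh")
        df["p_adj_bh"] = adj
    return df
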