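#!/usr/bin/env python
"""Gene-set over-representation of the significant gene lists.

Builds a synthetic gene-set collection (GMT) over the simulated genes —
one set seeded from genes carrying planted usage shifts plus random decoy
sets — then tests the differential-exon-usage and differential-isoform
gene lists against their expressed-gene backgrounds with the one-sided
hypergeometric (Fisher) test. Writes results/enrichment_{deu,die}.tsv and
the generated results/data/gene_sets.gmt.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from splicemeth import enrichment

DATA = Path("results/data")


def build_gmt(all_genes, seeded, path, rng):
    """One set enriched for the seeded genes + 19 random decoys."""
    lines = []
    seeded = sorted(seeded)[:30]
    pad = list(rng.choice(sorted(set(all_genes) - set(seeded)), size=10,
                          replace=False))
    lines.append("SET_SEEDED\tplanted usage machinery\t" + "\t".join(seeded + pad))
    for i in range(19):
        size = int(rng.integers(10, 40))
        members = rng.choice(sorted(all_genes), size=size, replace=False)
        lines.append(f"SET_RND{i:02d}\trandom decoy\t" + "\t".join(members))
    Path(path).write_text("\n".join(lines) + "\n")


def main() -> None:
    rng = np.random.default_rng(20)
    deu = pd.read_csv("results/deu_results.tsv", sep="\t")
    die = pd.read_csv("results/die_results.tsv", sep="\t")
    truth_deu = pd.read_csv(DATA / "truth_deu.tsv", sep="\t")

    bg_deu = set(deu.gene_id)
    sig_deu = set(deu[deu.significant].gene_id)
    bg_die = set(die.gene_id)
    sig_die = set(die[die.significant].gene_id)

    gmt_path = DATA / "gene_sets.gmt"
    build_gmt(bg_deu, set(truth_deu.gene_id), gmt_path, rng)
    sets = enrichment.read_gmt(str(gmt_path))

    for label, sig, bg in (("deu", sig_deu, bg_deu), ("die", sig_die, bg_die)):
        res = enrichment.fisher_enrichment(sig & bg, bg, sets)
        df = enrichment.results_frame(res)
        df.to_csv(f"results/enrichment_{label}.tsv", sep="\t", index=False)
        top = df.iloc[0]
        print(f"{label.upper()}: {len(sig)} significant / {len(bg)} background; "
              f"top term {top.term_id} p={top.p_value:.3g} "
              f"({top.n_sig}/{top.n_total} genes)")


if __name__ == "__main__":
    sys.exit(main())
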