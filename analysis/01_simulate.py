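#!/usr/bin/env python
"""Generate the synthetic study dataset.

Emulates the emulated trial's design — 9 control vs 10 treatment RNA
samples, 7 vs 9 bisulfite samples — over 300 genes, with 10 % differentially
expressed isoforms (log2FC 2), 30 % of genes carrying a x4 usage shift on
one minor exon bin, a 4 % background DM-site rate and a 5-fold DM enrichment
inside differentially used bins and their flanking introns.

Writes annotation (GTF), count matrices, design tables, per-sample Bismark
style cytosine reports and the ground-truth tables under results/data/.
"""

import sys
from pathlib import Path

from splicemeth import simulate
from splicemeth.annotation import write_gtf
from splicemeth.methylation import write_cytosine_report

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SimulationConfig(seed=SEED, n_genes=300)
    genes, iso, bins, design_rna, design_meth, meth, truth = simulate.simulate_all(cfg)

    write_gtf(genes, str(OUT / "annotation.gtf"))
    iso.to_csv(OUT / "isoform_counts.tsv", sep="\t")
    bins.to_csv(OUT / "bin_counts.tsv", sep="\t", index=False)
    design_rna.to_csv(OUT / "design_rna.tsv", sep="\t", index=False)
    design_meth.to_csv(OUT / "design_meth.tsv", sep="\t", index=False)
    for sid in meth.sample_ids:
        write_cytosine_report(meth, sid, str(OUT / f"cytosine_report_{sid}.tsv"))
    for key, df in truth.to_frames().items():
        df.to_csv(OUT / f"truth_{key}.tsv", sep="\t", index=False)

    print(f"seed {SEED}: {len(genes)} genes, {len(iso)} isoforms, "
          f"{len(bins)} exon bins, {len(meth.sites)} cytosine records")
    print(f"planted: {len(truth.die_isoforms)} DIE isoforms, "
          f"{len(truth.deu_bins)} DEU bins, {len(truth.dm_sites)} DM sites")
    print(f"wrote inputs to {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
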