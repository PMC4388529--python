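"""Call gains and losses relative to ploidy; find recurrent and significant regions.

Reads the cohort from ``results/cohort``, removes mask-dominated segments,
projects segment calls onto genes (gain/loss when the copy number deviates
from tumour ploidy by more than 0.9 over at least 10 markers), reports genes
altered in at least 20% of samples, and delimits significantly altered
regions with the cyclic-shift permutation scorer (q < 0.25).  Tables go to
``results/02_calls``.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from cnmod.io import FLOAT_FORMAT, read_bed, read_genome_map, read_profiles, write_matrix
from cnmod.segments import (
    gene_level_calls,
    mask_segments,
    recurrence_filter,
    score_regions,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT, OUT = ROOT / "cohort", ROOT / "02_calls"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = read_profiles(COHORT / "segments.seg", COHORT / "ploidy.tsv")
    masks = read_bed(COHORT / "masks.bed")
    genome_map = read_genome_map(COHORT / "genome_map.tsv")

    profiles = [mask_segments(p, masks) for p in profiles]
    cm = gene_level_calls(profiles, genome_map)
    write_matrix(cm.calls, OUT / "call_matrix.tsv")
    write_matrix(cm.cn, OUT / "cn_matrix.tsv")

    rec = recurrence_filter(cm)
    rec.frequencies.reset_index(names="gene").to_csv(
        OUT / "frequencies.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    scan = score_regions(cm, profiles, genome_map, n_perm=200, seed=SEED)
    scan.gene_table.to_csv(OUT / "region_gene_scores.tsv", sep="\t", index=False,
                           float_format=FLOAT_FORMAT)
    pd.DataFrame(
        [{"chrom": r.interval.chrom, "start": r.interval.start, "end": r.interval.end,
          "direction": r.direction, "score": r.score, "q": r.q}
         for r in scan.regions]
    ).to_csv(OUT / "regions.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    print(f"called {cm.shape[0]} genes x {cm.shape[1]} samples")
    print(f"  gain-recurrent: {len(rec.gain_genes)}, loss-recurrent: {len(rec.loss_genes)}")
    print(f"  significant regions (q<0.25): {len(scan.regions)}")


if __name__ == "__main__":
    main()
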