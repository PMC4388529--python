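"""Annotate modules by gene-set enrichment; stratify survival by copy number.

Tests each detected module for over-representation of the bundled gene sets
against the interactome background (hypergeometric, BH-FDR), then screens
copy-number-lost network genes for prognostic effect (log-rank of lost vs
neutral samples, gained samples excluded) and compares survival between
high-ploidy (>3n) and remaining samples.  Tables go to ``results/06_annotation``.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from cnmod.annotate import enrich_modules, enrichment_table
from cnmod.io import (
    FLOAT_FORMAT,
    read_genome_map,
    read_gmt,
    read_interactome,
    read_matrix,
    read_profiles,
    read_survival,
)
from cnmod.modules import ModulePartition
from cnmod.segments import CallMatrix
from cnmod.survival import gene_survival_screen, ploidy_survival

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "06_annotation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    interactome = read_interactome(ROOT / "cohort" / "interactome.tsv")
    gene_sets = read_gmt(ROOT / "cohort" / "gene_sets.gmt")
    assignment = pd.read_csv(
        ROOT / "05_modules" / "module_assignment.tsv", sep="\t"
    )
    part = ModulePartition(
        assignment=dict(zip(assignment["gene"], assignment["module"])),
        modules=pd.DataFrame(), q=0.0,
    )
    enr = enrich_modules(part, gene_sets, set(interactome.nodes))
    enrichment_table(enr).to_csv(OUT / "enrichment.tsv", sep="\t", index=False,
                                 float_format=FLOAT_FORMAT)
    top = [r for r in enr if r.q < 0.05]

    calls = read_matrix(ROOT / "02_calls" / "call_matrix.tsv")
    cn = read_matrix(ROOT / "02_calls" / "cn_matrix.tsv")
    cm = CallMatrix(calls.astype(int), cn)
    surv = read_survival(ROOT / "cohort" / "survival.tsv")
    attrs = pd.read_csv(
        ROOT / "04_network" / "cytoscape" / "node_attributes.tsv", sep="\t"
    )
    loss_drivers = set(
        attrs.loc[(attrs["role"] == "driver") & (attrs["alteration"] == "loss"), "gene"]
    )
    screen = gene_survival_screen(cm, surv, loss_drivers)
    screen.to_csv(OUT / "survival_screen.tsv", sep="\t", index=False,
                  float_format=FLOAT_FORMAT)

    profiles = read_profiles(ROOT / "cohort" / "segments.seg", ROOT / "cohort" / "ploidy.tsv")
    tested = screen[screen["skipped"] == ""]
    print(f"enrichment: {len(enr)} module x term tests, {len(top)} at q < 0.05")
    print(f"survival screen: {len(tested)}/{len(screen)} loss genes testable; "
          f"min p = {tested['p'].min():.4f}" if len(tested) else "no testable genes")
    try:
        plo = ploidy_survival(profiles, surv)
        plo.curves.to_csv(OUT / "ploidy_km_curves.tsv", sep="\t", index=False,
                          float_format=FLOAT_FORMAT)
        print(f"ploidy > 3n vs rest: chi-square {plo.statistic:.2f}, p = {plo.p:.3f} "
              f"(groups {plo.group_sizes})")
    except ValueError as exc:
        print(f"ploidy comparison unavailable: {exc}")


if __name__ == "__main__":
    main()
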