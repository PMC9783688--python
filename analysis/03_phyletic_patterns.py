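#!/usr/bin/env python
"""Classify the gain/loss phyletic pattern of each significant family.

Dollo-reconstructs every family flagged by 02_differential_representation.py
on the species tree and assigns it a pattern (punctuated clade loss, gradual
loss, clade-exclusive gain, expansion, background), then compares the calls
with the planted truth.  Writes results/patterns/phyletic_patterns.tsv and a
per-category confusion table.
"""

from pathlib import Path

import pandas as pd

from orthonod import (
    PlantedTruth,
    classify_orthogroups,
    default_scenario,
    read_gene_counts,
    read_species_metadata,
    read_tree,
    default_focal_clades,
)
from orthonod.report import patterns_to_frame

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulation"
DIFF = ROOT / "results" / "diffrep"
OUT = ROOT / "results" / "patterns"
SEED = 7  # must match 01_simulate.py


def main() -> None:
    panel = read_species_metadata(SIM / "species_metadata.tsv")
    matrix = read_gene_counts(SIM / "Orthogroups.GeneCount.tsv")
    tree = read_tree(SIM / "species_tree.nwk", panel)
    truth = PlantedTruth.from_frame(pd.read_csv(SIM / "planted_truth.tsv", sep="\t"))
    diffrep = pd.read_csv(DIFF / "diffrep.tsv", sep="\t")
    sig = sorted(
        set(
            diffrep.loc[
                diffrep["significant_presence"] | diffrep["significant_count"],
                "orthogroup",
            ]
        )
    )

    focal = default_focal_clades(default_scenario(SEED), panel)
    patterns = classify_orthogroups(matrix, tree, panel, focal, sig)
    OUT.mkdir(parents=True, exist_ok=True)
    frame = patterns_to_frame(patterns)
    frame.to_csv(OUT / "phyletic_patterns.tsv", sep="\t", index=False)

    frame["planted_category"] = frame["orthogroup"].map(truth.category)
    confusion = (
        frame.groupby(["planted_category", "category"]).size().unstack(fill_value=0)
    )
    confusion.to_csv(OUT / "category_confusion.tsv", sep="\t")
    print(f"classified {len(frame)} significant families")
    print(confusion)


if __name__ == "__main__":
    main()
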