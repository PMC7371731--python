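"""Simulate the study cohorts and write them out for inspection.

Generates the in-vitro senescence training comparison, its linked
application cohort, and the paired mouse/human cohorts with an ortholog
map, and writes matrices, annotations, planted truth and the map under
results/cohorts/. The planted GMTs are the ground truth the later
drivers are judged against.
"""

import importlib
import sys
from pathlib import Path

from suvarness.io import (
    write_annotations,
    write_expression_matrix,
    write_gmt,
    write_ortholog_map,
)
from suvarness.simulate import generate_paired_species_cohorts, generate_tis_study

sys.path.insert(0, str(Path(__file__).resolve().parent))
config = importlib.import_module("00_config")

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
OUT.mkdir(parents=True, exist_ok=True)


def dump(cohort, stem):
    write_expression_matrix(cohort.expression, OUT / f"{stem}_matrix.tsv")
    write_annotations(cohort.annotation, OUT / f"{stem}_annotation.csv")
    write_gmt([cohort.planted.up, cohort.planted.down], OUT / f"{stem}_planted.gmt")
    groups = cohort.annotation["outcome_group"].value_counts().to_dict()
    print(f"{stem}: {cohort.expression.shape[0]} genes x "
          f"{cohort.expression.shape[1]} samples, groups {groups}, "
          f"{len(cohort.planted.up)} up / {len(cohort.planted.down)} down planted")


training, application = generate_tis_study(config.STUDY.cohort)
dump(training, "tis_training")
dump(application, "tis_application")

mouse, human, omap = generate_paired_species_cohorts(
    config.STUDY.cohort, overlap_fraction=1.0, half_down=True
)
dump(mouse, "mouse")
dump(human, "human")
write_ortholog_map(omap, OUT / "orthologs.tsv")
print(f"ortholog map: {len(omap)} one-to-one pairs")
print(f"wrote cohorts to {OUT}")
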