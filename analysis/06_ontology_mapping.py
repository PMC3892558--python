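"""Level-1 mapping of the simulated terminal terms, broken down by Venn
group.

Each matrix trait doubles as a terminal term of the simulated 16-category
molecular-function DAG; the climb to level-1 parents yields the per-
category, per-group count table and the mapped percentage.

Run after 01_simulate_dataset.py and 02_venn_census.py.
"""

from pathlib import Path

import pandas as pd

from phyletica import (
    assign_venn_groups,
    level1_breakdown,
    load_ontology,
    load_organism_metadata,
    load_trait_matrix,
    mapped_percentage,
)
from phyletica.venn import VENN_GROUPS

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    matrix = load_trait_matrix(DATA / "matrix.tsv")
    metadata = load_organism_metadata(DATA / "metadata.tsv")
    dag = load_ontology(DATA / "ontology.obo")
    assignments = assign_venn_groups(matrix, metadata)
    terminals = {a.trait_id: a.group for a in assignments}
    breakdown = level1_breakdown(terminals, dag)

    rows = []
    for l1 in sorted({k[0] for k in breakdown.counts}):
        row = {"level1_id": l1, "level1_name": dag.name_of(l1)}
        row.update({g: breakdown.counts.get((l1, g), 0) for g in VENN_GROUPS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(OUT / "level1_breakdown.tsv", sep="\t", index=False)

    print(f"{breakdown.n_mapped} of {breakdown.n_submitted} terminals mapped "
          f"to {len(breakdown.groups_per_level1)} level-1 categories "
          f"({mapped_percentage(breakdown)}%)")
    unique = {l1: groups for l1, groups in breakdown.groups_per_level1.items()
              if len(groups) == 1}
    if unique:
        print("level-1 categories fed by a single Venn group:")
        for l1, groups in sorted(unique.items()):
            print(f"  {dag.name_of(l1)}: {next(iter(groups))}")
    else:
        print("no level-1 category is uniquely attributable to one Venn group")


if __name__ == "__main__":
    main()
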