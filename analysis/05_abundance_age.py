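"""Genomic abundance as a relative-age proxy.

Sums each organism's trait copies per Venn group and summarises them on a
log10(x+1) scale.  Expected signature of duplication growth: the
urancestral ABE group has the highest median abundance in every
superkingdom, and mean copy number decreases with birth epoch.

Run after 01_simulate_dataset.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phyletica import (
    GroundTruth,
    assign_venn_groups,
    group_abundance,
    load_organism_metadata,
    load_trait_matrix,
    summarize_abundance,
)
from phyletica.io import SUPERKINGDOMS
from phyletica.venn import VENN_GROUPS

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    matrix = load_trait_matrix(DATA / "matrix.tsv")
    metadata = load_organism_metadata(DATA / "metadata.tsv")
    truth = GroundTruth.from_json(DATA / "truth.json")
    assignments = assign_venn_groups(matrix, metadata)
    profiles = group_abundance(matrix, assignments, metadata)

    rows = []
    for group in VENN_GROUPS:
        for sk in SUPERKINGDOMS:
            if sk not in group:
                continue
            s = summarize_abundance(profiles, group, sk)
            if s is None:
                continue
            lo, q1, med, q3, hi = (round(v, 3) for v in s.five_number)
            rows.append(dict(group=group, superkingdom=sk, n=s.n_organisms,
                             min=lo, q1=q1, median=med, q3=q3, max=hi,
                             n_outliers=len(s.outliers),
                             argmax=s.argmax_id, argmin=s.argmin_id))
    pd.DataFrame(rows).to_csv(OUT / "abundance_summary.tsv", sep="\t", index=False)

    by_epoch: dict[int, list[int]] = {}
    for t in truth.traits.values():
        row = matrix.abundance.loc[t.trait_id]
        by_epoch.setdefault(t.birth_epoch, []).extend(row[row >= 1].tolist())
    print("mean copy number per present trait, by birth epoch:")
    for e in sorted(by_epoch):
        print(f"  epoch {e}: {np.mean(by_epoch[e]):8.2f}")
    df = pd.DataFrame(rows)
    abe = df[df.group == "ABE"].set_index("superkingdom")["median"]
    print("ABE median log10(abundance+1) by superkingdom:",
          ", ".join(f"{sk}={abe[sk]}" for sk in SUPERKINGDOMS))


if __name__ == "__main__":
    main()
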