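"""Per-superkingdom spread (f-values) of the simulated traits.

Computes one f-profile per trait, panel summaries per (Venn group,
superkingdom), and the universal / near-universal cores.  Expected
signature: ABE medians are high everywhere but lowest in Archaea (patchy
archaeal lineage loss), and superkingdom-specific traits show low spread.

Run after 01_simulate_dataset.py.
"""

from pathlib import Path

import pandas as pd

from phyletica import (
    assign_venn_groups,
    load_organism_metadata,
    load_trait_matrix,
    near_universal,
    spread_profiles,
    summarize_spread,
    universal_core,
)
from phyletica.display import display_f
from phyletica.io import SUPERKINGDOMS
from phyletica.venn import VENN_GROUPS

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    matrix = load_trait_matrix(DATA / "matrix.tsv")
    metadata = load_organism_metadata(DATA / "metadata.tsv")
    assignments = assign_venn_groups(matrix, metadata)
    profiles = spread_profiles(matrix, metadata, assignments)

    rows = []
    for group in VENN_GROUPS:
        for sk in SUPERKINGDOMS:
            if sk not in group:
                continue
            s = summarize_spread(profiles, group, sk)
            if s is None:
                continue
            rows.append(
                dict(group=group, superkingdom=sk, n=s.n_traits,
                     q1=round(s.quartiles[0], 3), median=round(s.median_f, 2),
                     q3=round(s.quartiles[1], 3), n_tail=s.n_tail)
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "spread_summary.tsv", sep="\t", index=False)

    core = universal_core(matrix)
    near = near_universal(matrix, 0.90)
    (OUT / "universal_core.txt").write_text("\n".join(core) + "\n")
    print(f"universal core: {len(core)} traits present in all "
          f"{matrix.n_organisms} organisms")
    print(f"near-universal (overall f > 0.90): {len(near)} traits")
    abe = summary[summary.group == "ABE"].set_index("superkingdom")["median"]
    print("ABE median f by superkingdom:",
          ", ".join(f"{sk}={abe[sk]}" for sk in SUPERKINGDOMS))
    rare = min(
        (f for p in profiles for f in p.f_by_superkingdom.values()),
    )
    print(f"least-spread defined f in the dataset: {display_f(rare)}")


if __name__ == "__main__":
    main()
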