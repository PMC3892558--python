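"""nd-based evolutionary timelines of the simulated traits.

Reads the epoch-consistent trait tree, derives node-distance ages
(0 = most ancient, 1 = most derived), joins them with Venn groups and
per-superkingdom abundances, and reports the most ancient trait per
group.  Expected signature: ABE and BE groups appear at nd = 0, the first
Bacteria-specific novelty precedes the joint Archaea-/Eukarya-specific
innovations.

Run after 01_simulate_dataset.py.
"""

import json
from pathlib import Path

import pandas as pd

from phyletica import (
    GroundTruth,
    assign_venn_groups,
    build_timeline,
    load_organism_metadata,
    load_trait_matrix,
    load_trait_tree,
    most_ancient_per_group,
    node_distance,
)
from phyletica.io import SUPERKINGDOMS

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    matrix = load_trait_matrix(DATA / "matrix.tsv")
    metadata = load_organism_metadata(DATA / "metadata.tsv")
    truth = GroundTruth.from_json(DATA / "truth.json")
    tree = load_trait_tree(DATA / "tree.nwk")
    nd_map = node_distance(tree)
    assignments = assign_venn_groups(matrix, metadata)
    entries = build_timeline(nd_map, assignments, matrix, metadata)

    pd.DataFrame(
        [
            dict(trait_id=e.trait_id, nd=round(e.nd, 4), venn_group=e.venn_group,
                 **{f"abundance_{sk}": e.abundance_by_superkingdom[sk]
                    for sk in SUPERKINGDOMS})
            for e in entries
        ]
    ).to_csv(OUT / "timeline.tsv", sep="\t", index=False)

    ancients = most_ancient_per_group(entries)
    (OUT / "most_ancient.json").write_text(json.dumps(ancients, indent=2))
    print(f"{len(entries)} traits placed on the timeline")
    print("most ancient trait per Venn group (nd, class):")
    nd_of = {e.trait_id: e.nd for e in entries}
    for group in ("ABE", "BE", "AB", "AE", "B", "A", "E"):
        tid = ancients.get(group)
        if tid is None:
            continue
        cls = truth.traits[tid].trait_class
        print(f"  {group:>3}: {tid}  nd={nd_of[tid]:.2f}  ({cls})")
    first = {cls: min(nd_of[t.trait_id] for t in truth.traits.values()
                      if t.trait_class == cls)
             for cls in ("b_specific", "a_specific", "e_specific")}
    print(f"first superkingdom-specific appearances: "
          f"B at nd={first['b_specific']:.2f}, A at nd={first['a_specific']:.2f}, "
          f"E at nd={first['e_specific']:.2f}")


if __name__ == "__main__":
    main()
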