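"""Ground-truthed synthetic repertoires under a superkingdom-diversification
scenario.

The generator emulates the genome-content history the comparative analysis
is designed to detect:

* an urancestral trait core born in epoch 0 and initially present in every
  organism of the three superkingdom blocks;
* early archaeal stem loss: each core trait is removed from *all* archaeal
  organisms with probability ``archaeal_loss_rate``, turning true
  urancestral traits into BE traits and enriching the BE group;
* patchy within-superkingdom loss on archaeal lineages
  (``archaeal_lineage_loss_rate``, per trait x archaeal organism), which
  lowers archaeal f-values of surviving ABE traits without changing their
  Venn class;
* ordered superkingdom-specific innovation: Bacteria-specific traits are
  born in epoch 1, Archaea- and Eukarya-specific traits jointly in epoch 2,
  each trait seeded into a random fraction of its block;
* relatively late reductive evolution in Bacteria: a random subset of
  bacterial organisms is flagged reduced and independently drops a fraction
  of its traits;
* duplication-driven abundance growth: the expected copy number of a trait
  scales as ``duplication_growth ** (current_epoch - birth_epoch)``, so
  older traits are more abundant (copy numbers are geometric draws, a
  light-tailed positive integer distribution);
* sparse planted transfers: each transfer trait is given a near-ubiquitous
  spread in its donor superkingdom and a scarce spread in its recipient,
  drawn from configurable ranges.  Transfers are planted as spread
  patterns, not event histories, because the detector observes spreads
  only.

Every emitted trait carries a ground-truth record (generative class, birth
epoch, transfer donor/recipient), so recovery by the census, spread, HGT
and timeline stages can be scored exactly.  Output is bit-deterministic
given the parameter set and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    SUPERKINGDOMS,
    OrganismRecord,
    TraitMatrix,
    write_organism_metadata,
)
from .ontology import OntologyDAG, build_dag, write_obo

__all__ = [
    "ScenarioParams",
    "TraitTruth",
    "GroundTruth",
    "simulate_repertoires",
    "simulate_ontology",
    "simulate_trait_tree",
    "write_fixture_bundle",
]

HGT_DIRECTIONS = (
    ("A", "B"),
    ("B", "A"),
    ("A", "E"),
    ("E", "A"),
    ("B", "E"),
    ("E", "B"),
)


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of the diversification scenario (defaults: the 981-proteome,
    ~1,700-trait structure-census conditions).

    ``n_organisms`` and ``n_specific`` are (Archaea, Bacteria, Eukarya)
    triples.  Epochs are integer ticks of a single global clock; Bacteria-
    specific birth precedes the joint Archaea/Eukarya-specific birth.
    """

    n_organisms: tuple[int, int, int] = (70, 652, 259)
    n_core: int = 1110
    n_specific: tuple[int, int, int] = (10, 164, 373)
    birth_epochs: Mapping[str, int] = field(
        default_factory=lambda: {
            "core": 0,
            "b_specific": 1,
            "a_specific": 2,
            "e_specific": 2,
            "hgt": 1,
        }
    )
    archaeal_loss_rate: float = 0.29
    archaeal_lineage_loss_rate: float = 0.25
    late_bacterial_loss_rate: float = 0.10
    reduction_depth: float = 0.5
    duplication_growth: float = 4.0
    base_abundance_mean: float = 3.0
    specific_spread: tuple[float, float] = (0.05, 0.6)
    n_hgt: int = 30
    donor_spread: tuple[float, float] = (0.9, 1.0)
    recipient_spread: tuple[float, float] = (0.0, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "archaeal_loss_rate",
            "archaeal_lineage_loss_rate",
            "late_bacterial_loss_rate",
            "reduction_depth",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if any(n < 1 for n in self.n_organisms):
            raise ConfigurationError("every superkingdom needs >= 1 organism")
        if self.n_core < 0 or self.n_hgt < 0 or any(n < 0 for n in self.n_specific):
            raise ConfigurationError("trait counts must be non-negative")
        if self.duplication_growth < 1.0:
            raise ConfigurationError("duplication_growth must be >= 1")
        if self.base_abundance_mean < 1.0:
            raise ConfigurationError("base_abundance_mean must be >= 1")
        for name in ("specific_spread", "donor_spread", "recipient_spread"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must be an ordered range in [0, 1]")
        if self.birth_epochs["b_specific"] >= self.birth_epochs["a_specific"]:
            raise ConfigurationError(
                "scenario requires Bacteria-specific birth before the joint "
                "Archaea/Eukarya-specific epoch"
            )

    @property
    def current_epoch(self) -> int:
        return max(self.birth_epochs.values())

    def replace(self, **kwargs) -> "ScenarioParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TraitTruth:
    """Generative record of one trait."""

    trait_id: str
    trait_class: str  # urancestral | be_stem | a/b/e_specific | hgt
    birth_epoch: int
    hgt_donor: str | None = None
    hgt_recipient: str | None = None


@dataclass
class GroundTruth:
    """Per-trait truth records plus per-organism reduction flags."""

    traits: dict[str, TraitTruth]
    reduced_organisms: frozenset[str]
    extinct: tuple[str, ...] = ()

    def expected_group(self, trait_id: str) -> str:
        """Venn group implied by the generative class alone (valid when no
        stochastic loss/reduction interferes)."""
        t = self.traits[trait_id]
        if t.trait_class == "hgt":
            return "".join(sorted({t.hgt_donor, t.hgt_recipient}))
        return {
            "urancestral": "ABE",
            "be_stem": "BE",
            "a_specific": "A",
            "b_specific": "B",
            "e_specific": "E",
        }[t.trait_class]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "traits": {
                t.trait_id: {
                    "trait_class": t.trait_class,
                    "birth_epoch": t.birth_epoch,
                    "hgt_donor": t.hgt_donor,
                    "hgt_recipient": t.hgt_recipient,
                }
                for t in self.traits.values()
            },
            "reduced_organisms": sorted(self.reduced_organisms),
            "extinct": list(self.extinct),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        traits = {
            tid: TraitTruth(trait_id=tid, **rec)
            for tid, rec in payload["traits"].items()
        }
        return cls(
            traits=traits,
            reduced_organisms=frozenset(payload["reduced_organisms"]),
            extinct=tuple(payload["extinct"]),
        )


def _organism_ids(params: ScenarioParams) -> tuple[list[str], dict[str, slice]]:
    n_a, n_b, n_e = params.n_organisms
    ids, blocks, start = [], {}, 0
    for sk, n in zip(SUPERKINGDOMS, (n_a, n_b, n_e)):
        ids.extend(f"{sk}_{i:04d}" for i in range(1, n + 1))
        blocks[sk] = slice(start, start + n)
        start += n
    return ids, blocks


def simulate_repertoires(
    params: ScenarioParams,
) -> tuple[TraitMatrix, list[OrganismRecord], GroundTruth]:
    """Generate a trait matrix, organism metadata and ground truth."""
    rng = np.random.default_rng(params.seed)
    org_ids, blocks = _organism_ids(params)
    n_orgs = len(org_ids)
    n_a, n_b, n_e = params.n_organisms
    block_sizes = dict(zip(SUPERKINGDOMS, (n_a, n_b, n_e)))

    trait_ids: list[str] = []
    truths: list[TraitTruth] = []
    presence_rows: list[np.ndarray] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"t{counter:05d}"

    # --- urancestral core, with archaeal stem loss -----------------------
    stem_lost = rng.random(params.n_core) < params.archaeal_loss_rate
    lineage_lost = rng.random((params.n_core, n_a)) < params.archaeal_lineage_loss_rate
    for i in range(params.n_core):
        row = np.ones(n_orgs, dtype=bool)
        if stem_lost[i]:
            row[blocks["A"]] = False
            cls = "be_stem"
        else:
            row[blocks["A"]] &= ~lineage_lost[i]
            if not row[blocks["A"]].any():
                # patchy loss emptied the block; keep one survivor so the
                # generative class stays observable (deterministic choice so
                # the rng stream is independent of the loss realisation)
                row[blocks["A"].start + (i % n_a)] = True
            cls = "urancestral"
        tid = new_id()
        trait_ids.append(tid)
        truths.append(TraitTruth(tid, cls, params.birth_epochs["core"]))
        presence_rows.append(row)

    # --- superkingdom-specific innovations -------------------------------
    for sk, n_traits, cls_name in zip(
        SUPERKINGDOMS, params.n_specific, ("a_specific", "b_specific", "e_specific")
    ):
        n_block = block_sizes[sk]
        for _ in range(n_traits):
            spread = rng.uniform(*params.specific_spread)
            mask = rng.random(n_block) < spread
            if not mask.any():
                mask[rng.integers(n_block)] = True
            row = np.zeros(n_orgs, dtype=bool)
            row[blocks[sk]] = mask
            tid = new_id()
            trait_ids.append(tid)
            truths.append(TraitTruth(tid, cls_name, params.birth_epochs[cls_name]))
            presence_rows.append(row)

    # --- planted transfers ------------------------------------------------
    for _ in range(params.n_hgt):
        donor, recipient = HGT_DIRECTIONS[rng.integers(len(HGT_DIRECTIONS))]
        s_d = rng.uniform(*params.donor_spread)
        s_r = rng.uniform(*params.recipient_spread)
        n_d, n_r = block_sizes[donor], block_sizes[recipient]
        k_d = min(n_d, int(np.ceil(s_d * n_d)))          # f_donor >= drawn spread
        k_r = max(1, int(np.floor(s_r * n_r)))           # f_recipient <= max(spread, 1/n)
        row = np.zeros(n_orgs, dtype=bool)
        donor_idx = rng.choice(n_d, size=k_d, replace=False)
        rec_idx = rng.choice(n_r, size=k_r, replace=False)
        row[donor_idx + blocks[donor].start] = True
        row[rec_idx + blocks[recipient].start] = True
        tid = new_id()
        trait_ids.append(tid)
        truths.append(
            TraitTruth(
                tid,
                "hgt",
                params.birth_epochs["hgt"],
                hgt_donor=donor,
                hgt_recipient=recipient,
            )
        )
        presence_rows.append(row)

    presence = (
        np.vstack(presence_rows)
        if presence_rows
        else np.zeros((0, n_orgs), dtype=bool)
    )

    # --- late reductive loss in Bacteria ---------------------------------
    reduced_flags = rng.random(n_b) < params.late_bacterial_loss_rate
    reduced_orgs = []
    for j in np.flatnonzero(reduced_flags):
        col = blocks["B"].start + j
        keep = rng.random(presence.shape[0]) >= params.reduction_depth
        presence[:, col] &= keep
        reduced_orgs.append(org_ids[col])

    # --- duplication-driven abundance ------------------------------------
    ages = np.array(
        [params.current_epoch - t.birth_epoch for t in truths], dtype=float
    )
    means = params.base_abundance_mean * params.duplication_growth**ages
    if presence.shape[0]:
        draws = rng.geometric(1.0 / means[:, None], size=presence.shape)
        abundance = draws * presence
    else:
        abundance = np.zeros((0, n_orgs), dtype=np.int64)

    # --- drop traits rendered extinct by reduction ------------------------
    alive = presence.any(axis=1)
    extinct_ids = tuple(np.array(trait_ids)[~alive])
    abundance = abundance[alive]
    kept_ids = list(np.array(trait_ids)[alive])
    kept_truths = {t.trait_id: t for t, a in zip(truths, alive) if a}

    matrix = TraitMatrix(
        pd.DataFrame(abundance.astype(np.int64), index=kept_ids, columns=org_ids),
        id_scheme="GENERIC",
    )
    coverage = rng.uniform(0.55, 0.95, size=n_orgs)
    metadata = [
        OrganismRecord(
            organism_id=org,
            superkingdom=org[0],
            lifestyle="free_living",
            annotation_coverage=round(float(c), 3),
        )
        for org, c in zip(org_ids, coverage)
    ]
    truth = GroundTruth(
        traits=kept_truths,
        reduced_organisms=frozenset(reduced_orgs),
        extinct=extinct_ids,
    )
    return matrix, metadata, truth


def simulate_ontology(
    n_level1: int = 16,
    n_terminal: int = 100,
    multi_parent_prob: float = 0.1,
    seed: int = 0,
    terminal_ids: Sequence[str] | None = None,
    n_intermediates_per_level1: int = 2,
) -> tuple[OntologyDAG, list[str]]:
    """Generate a rooted is_a DAG with level-1 categories and terminals.

    Terminals sit at depth >= 2 below their level-1 parent (terminal ->
    intermediate -> level-1 -> root); with probability ``multi_parent_prob``
    a terminal also attaches under a second level-1 subtree.  Acyclic by
    construction.  ``terminal_ids`` overrides the generated terminal names
    (and ``n_terminal``), so matrix trait ids can double as ontology terms.
    """
    if n_level1 < 1:
        raise ConfigurationError("need at least one level-1 term")
    rng = np.random.default_rng(seed)
    root = "SYN:0000000"
    names = {root: "molecular function root"}
    edges: list[tuple[str, str]] = []
    level1 = []
    intermediates: dict[str, list[str]] = {}
    nxt = 1
    for i in range(n_level1):
        l1 = f"SYN:{nxt:07d}"
        nxt += 1
        names[l1] = f"level1 category {i + 1}"
        edges.append((l1, root))
        level1.append(l1)
        intermediates[l1] = []
        for _ in range(max(1, n_intermediates_per_level1)):
            mid = f"SYN:{nxt:07d}"
            nxt += 1
            names[mid] = f"intermediate under category {i + 1}"
            edges.append((mid, l1))
            intermediates[l1].append(mid)
    if terminal_ids is None:
        terminal_ids = [f"SYN:{nxt + i:07d}" for i in range(n_terminal)]
    terminals = [str(t) for t in terminal_ids]
    for term in terminals:
        names.setdefault(term, f"terminal activity {term}")
        primary = level1[rng.integers(n_level1)]
        mids = intermediates[primary]
        edges.append((term, mids[rng.integers(len(mids))]))
        if n_level1 > 1 and rng.random() < multi_parent_prob:
            other_choices = [l for l in level1 if l != primary]
            other = other_choices[rng.integers(len(other_choices))]
            mids2 = intermediates[other]
            edges.append((term, mids2[rng.integers(len(mids2))]))
    dag = build_dag(edges, names=names, root=root)
    return dag, terminals


def simulate_trait_tree(truth: GroundTruth, seed: int = 0) -> dendropy.Tree:
    """Rooted tree whose leaf depths follow birth-epoch order.

    A pectinate backbone carries one polytomy per birth epoch (oldest at
    the root), so every leaf's root-path node count is strictly increasing
    in its birth epoch and tied within an epoch; leaf order inside an
    epoch is shuffled by the seed.  A single-epoch truth yields a star
    (all nd = 0).
    """
    rng = np.random.default_rng(seed)
    by_epoch: dict[int, list[str]] = {}
    for t in truth.traits.values():
        by_epoch.setdefault(t.birth_epoch, []).append(t.trait_id)
    if sum(len(v) for v in by_epoch.values()) < 2:
        raise ConfigurationError("trait tree needs at least 2 traits")
    epochs = sorted(by_epoch)
    shuffled = {}
    for e in epochs:
        leaves = sorted(by_epoch[e])
        rng.shuffle(leaves)
        shuffled[e] = leaves
    newick = None
    for e in reversed(epochs):
        inner = ",".join(shuffled[e])
        if newick is None:
            newick = f"({inner})"
        else:
            newick = f"({inner},{newick})"
    return dendropy.Tree.get(
        data=newick + ";", schema="newick", preserve_underscores=True
    )


def write_fixture_bundle(
    out_dir: str | Path, params: ScenarioParams
) -> dict[str, Path]:
    """Emit the exact file formats the pipeline consumes.

    Writes matrix.tsv, metadata.tsv, ontology.obo (terminals = matrix trait
    ids), tree.nwk, exclusion.txt (empty) and truth.json under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, metadata, truth = simulate_repertoires(params)
    paths = {
        "matrix": out / "matrix.tsv",
        "metadata": out / "metadata.tsv",
        "ontology": out / "ontology.obo",
        "tree": out / "tree.nwk",
        "exclusion": out / "exclusion.txt",
        "truth": out / "truth.json",
    }
    matrix.write_tsv(paths["matrix"])
    write_organism_metadata(metadata, paths["metadata"])
    dag, _ = simulate_ontology(
        seed=params.seed, terminal_ids=matrix.trait_ids
    )
    write_obo(dag, paths["ontology"])
    tree = simulate_trait_tree(truth, seed=params.seed)
    tree.write(path=str(paths["tree"]), schema="newick", unquoted_underscores=True)
    paths["exclusion"].write_text("# traits excluded from analysis\n")
    truth.to_json(paths["truth"])
    return paths
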