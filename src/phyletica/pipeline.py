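"""End-to-end orchestration: filter -> census -> spread -> HGT -> abundance
-> ontology mapping -> timeline.

Each stage's tables are written before the next stage runs, so partial
results survive a late failure.  Ontology and tree inputs are optional;
stages that need them are skipped with a notice in the report.  After all
stages, cross-module conservation identities (Venn sum, flux sum,
abundance sum) are audited and any violation aborts the run.

The analysis itself is deterministic; rerunning an identical configuration
reproduces every output byte (no timestamps are written).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import abundance as abundance_mod
from . import hgt as hgt_mod
from . import ontology as onto_mod
from . import spread as spread_mod
from . import timeline as timeline_mod
from . import venn as venn_mod
from .display import display_f
from .errors import ConfigurationError, ConsistencyError
from .io import (
    SUPERKINGDOMS,
    DatasetConfig,
    config_manifest,
    filter_dataset,
    load_exclusion_list,
    load_organism_metadata,
    load_trait_matrix,
    write_manifest,
)

__all__ = ["PipelineConfig", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    matrix: str
    metadata: str
    out_dir: str
    ontology: str | None = None
    tree: str | None = None
    exclusion: str | None = None
    id_scheme: str = "GENERIC"
    coverage_threshold: float = 0.5
    free_living_only: bool = False
    hgt_threshold: float = 0.6
    tail_threshold: float = 0.8
    near_universal_threshold: float = 0.90

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key/value YAML or JSON config document."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        missing = [k for k in ("matrix", "metadata", "out_dir") if k not in raw]
        if missing:
            raise ConfigurationError(f"{path}: missing mandatory key(s) {missing}")
        return cls(**raw)

    def dataset_config(self) -> DatasetConfig:
        exclusion = (
            load_exclusion_list(self.exclusion) if self.exclusion else frozenset()
        )
        return DatasetConfig(
            coverage_threshold=self.coverage_threshold,
            free_living_only=self.free_living_only,
            exclusion_list=exclusion,
            hgt_threshold=self.hgt_threshold,
            tail_threshold=self.tail_threshold,
            near_universal_threshold=self.near_universal_threshold,
        )


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _f_cell(profile, sk: str) -> str:
    f = profile.f_by_superkingdom.get(sk)
    return "" if f is None else f"{display_f(f):.3f}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all applicable stages in fixed order; returns the report dict."""
    for name, path in (("matrix", config.matrix), ("metadata", config.metadata)):
        if not Path(path).exists():
            raise ConfigurationError(f"mandatory input {name!r} not found: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset_config = config.dataset_config()
    matrix = load_trait_matrix(config.matrix, id_scheme=config.id_scheme)
    metadata = load_organism_metadata(config.metadata)
    manifest = config_manifest(
        dataset_config,
        inputs={
            "matrix": config.matrix,
            "metadata": config.metadata,
            "ontology": config.ontology,
            "tree": config.tree,
            "exclusion": config.exclusion,
        },
    )
    write_manifest(manifest, out / "manifest.json")

    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "skipped": []}

    # stage: filter ------------------------------------------------------
    filtered, filter_report = filter_dataset(matrix, metadata, dataset_config)
    report["filter"] = filter_report.to_dict()
    _write_json(report["filter"], out / "filter_report.json")

    # stage: census ------------------------------------------------------
    assignments = venn_mod.assign_venn_groups(filtered, metadata)
    counts = venn_mod.venn_counts(assignments)
    shares = {
        g: venn_mod.percentage_share(c, counts.total)
        for g, c in counts.counts.items()
        if counts.total
    }
    pd.DataFrame(
        [
            {
                "trait_id": a.trait_id,
                "present_A": int(a.presence[0]),
                "present_B": int(a.presence[1]),
                "present_E": int(a.presence[2]),
                "venn_group": a.group,
            }
            for a in assignments
        ]
    ).to_csv(out / "venn_assignments.tsv", sep="\t", index=False)
    report["venn"] = {"counts": counts.to_dict(), "shares_percent": shares}
    _write_json(report["venn"], out / "venn_counts.json")

    # stage: spread ------------------------------------------------------
    profiles = spread_mod.spread_profiles(filtered, metadata, assignments)
    pd.DataFrame(
        [
            {
                "trait_id": p.trait_id,
                "venn_group": p.venn_group,
                "f_A": _f_cell(p, "A"),
                "f_B": _f_cell(p, "B"),
                "f_E": _f_cell(p, "E"),
            }
            for p in profiles
        ]
    ).to_csv(out / "spread.tsv", sep="\t", index=False)
    summary_rows = []
    for group in venn_mod.VENN_GROUPS:
        for sk in SUPERKINGDOMS:
            if sk not in group:
                continue
            s = spread_mod.summarize_spread(
                profiles, group, sk, tail_threshold=dataset_config.tail_threshold
            )
            if s is None:
                continue
            summary_rows.append(
                {
                    "group": group,
                    "superkingdom": sk,
                    "n": s.n_traits,
                    "q1": round(s.quartiles[0], 4),
                    "median": round(s.median_f, 4),
                    "q3": round(s.quartiles[1], 4),
                    "n_tail": s.n_tail,
                }
            )
    pd.DataFrame(summary_rows).to_csv(out / "spread_summary.tsv", sep="\t", index=False)
    core = spread_mod.universal_core(filtered)
    near = spread_mod.near_universal(
        filtered, threshold=dataset_config.near_universal_threshold
    )
    (out / "universal_core.txt").write_text("\n".join(core) + "\n" if core else "")
    (out / "near_universal.txt").write_text("\n".join(near) + "\n" if near else "")
    report["spread"] = {
        "n_universal": len(core),
        "n_near_universal": len(near),
        "panels": summary_rows,
    }

    # stage: HGT ---------------------------------------------------------
    calls = hgt_mod.detect_all(profiles, threshold=dataset_config.hgt_threshold)
    tally = hgt_mod.tally_flux(calls, assignments)
    pd.DataFrame(
        [
            {
                "trait_id": c.trait_id,
                "group": c.group,
                "f_former": f"{display_f(c.f_former):.3f}",
                "f_latter": f"{display_f(c.f_latter):.3f}",
                "f_difference": f"{c.f_difference:+.3f}",
                "donor": c.donor,
                "recipient": c.recipient,
            }
            for c in calls
        ]
    ).to_csv(out / "hgt_calls.tsv", sep="\t", index=False)
    report["hgt"] = tally.to_dict()
    _write_json(report["hgt"], out / "flux_tally.json")

    # stage: abundance ---------------------------------------------------
    ab_profiles = abundance_mod.group_abundance(filtered, assignments, metadata)
    pd.DataFrame(
        [
            {
                "organism_id": p.organism_id,
                "superkingdom": p.superkingdom,
                **{f"abundance_{g}": p.per_group_abundance[g] for g in venn_mod.VENN_GROUPS},
            }
            for p in ab_profiles
        ]
    ).to_csv(out / "abundance_profiles.tsv", sep="\t", index=False)
    ab_rows = []
    for group in venn_mod.VENN_GROUPS:
        for sk in SUPERKINGDOMS:
            if sk not in group:
                continue
            s = abundance_mod.summarize_abundance(ab_profiles, group, sk)
            if s is None:
                continue
            lo, q1, med, q3, hi = (round(v, 4) for v in s.five_number)
            ab_rows.append(
                {
                    "group": group,
                    "superkingdom": sk,
                    "n": s.n_organisms,
                    "min": lo,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "max": hi,
                    "outlier_ids": ";".join(s.outliers),
                    "argmax_id": s.argmax_id,
                    "argmin_id": s.argmin_id,
                }
            )
    pd.DataFrame(ab_rows).to_csv(out / "abundance_summary.tsv", sep="\t", index=False)
    report["abundance"] = {"panels": ab_rows}

    # stage: ontology mapping (optional) ---------------------------------
    if config.ontology and Path(config.ontology).exists():
        dag = onto_mod.load_ontology(config.ontology)
        terminals = {a.trait_id: a.group for a in assignments}
        breakdown = onto_mod.level1_breakdown(terminals, dag)
        rows = []
        for l1 in sorted({k[0] for k in breakdown.counts}):
            row = {"level1_id": l1, "level1_name": dag.name_of(l1)}
            for g in venn_mod.VENN_GROUPS:
                row[g] = breakdown.counts.get((l1, g), 0)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "level1_breakdown.tsv", sep="\t", index=False)
        pd.DataFrame(
            breakdown.unmapped_ids, columns=["trait_id", "reason"]
        ).to_csv(out / "unmapped_terms.tsv", sep="\t", index=False)
        report["ontology"] = {
            "n_mapped": breakdown.n_mapped,
            "n_unmapped": breakdown.n_unmapped,
            "mapped_percent": onto_mod.mapped_percentage(breakdown)
            if breakdown.n_submitted
            else None,
            "n_level1_with_terminals": len(breakdown.groups_per_level1),
        }
    else:
        report["skipped"].append("ontology")

    # stage: timeline (optional) -----------------------------------------
    if config.tree and Path(config.tree).exists():
        tree = timeline_mod.load_trait_tree(config.tree)
        nd_map = timeline_mod.node_distance(tree)
        entries = timeline_mod.build_timeline(nd_map, assignments, filtered, metadata)
        pd.DataFrame(
            [
                {
                    "trait_id": e.trait_id,
                    "nd": round(e.nd, 6),
                    "venn_group": e.venn_group,
                    **{
                        f"abundance_{sk}": e.abundance_by_superkingdom[sk]
                        for sk in SUPERKINGDOMS
                    },
                }
                for e in entries
            ]
        ).to_csv(out / "timeline.tsv", sep="\t", index=False)
        ancients = timeline_mod.most_ancient_per_group(entries)
        _write_json(ancients, out / "most_ancient.json")
        report["timeline"] = {
            "n_entries": len(entries),
            "n_dropped": len(assignments) - len(entries),
            "most_ancient": ancients,
        }
    else:
        report["skipped"].append("tree")

    _audit(report, filtered, counts, tally, ab_profiles)
    _write_json(report, out / "report.json")
    return report


def _audit(report, filtered, counts, tally, ab_profiles) -> None:
    """Cross-module conservation identities; raise on any violation."""
    if sum(counts.counts.values()) != counts.total or counts.total != filtered.n_traits:
        raise ConsistencyError("Venn counts do not sum to the retained trait total")
    for g in venn_mod.TWO_SK_GROUPS:
        if sum(tally.counts[g].values()) + tally.n_vertical[g] != tally.group_sizes[g]:
            raise ConsistencyError(f"flux conservation violated for group {g}")
    column_totals = filtered.abundance.sum(axis=0)
    for p in ab_profiles:
        if p.total != int(column_totals[p.organism_id]):
            raise ConsistencyError(
                f"abundance conservation violated for organism {p.organism_id}"
            )
    report["audit"] = "passed"
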