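"""Loading, validation and filtering of trait repertoires.

The analysis substrate is an organism x trait *abundance* matrix: rows are
molecular traits (SCOP-style fold-superfamily identifiers such as ``c.37.1``,
GO identifiers such as ``GO:0008658``, or generic labels), columns are
organisms, and cells are non-negative integer copy counts.  *Occurrence*
(presence/absence) is always derived as ``abundance >= 1`` and never stored
separately.

Dataset construction applies three curation rules before any analysis:

* organisms below an annotation-coverage threshold are dropped (inclusive
  comparison: an organism at exactly the threshold is retained),
* optionally only free-living organisms are kept,
* traits on an explicit exclusion list (e.g. transfer-suspect annotations)
  are removed, and traits left with zero occurrence after organism filtering
  are dropped with a reported count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    MatrixParseError,
    SchemeMismatchError,
    ValidationError,
)

__all__ = [
    "SUPERKINGDOMS",
    "LIFESTYLES",
    "TraitMatrix",
    "OrganismRecord",
    "DatasetConfig",
    "FilterReport",
    "load_trait_matrix",
    "load_organism_metadata",
    "write_organism_metadata",
    "load_exclusion_list",
    "filter_dataset",
    "normalize_superkingdom",
    "config_manifest",
]

SUPERKINGDOMS = ("A", "B", "E")
LIFESTYLES = ("free_living", "parasitic", "unknown")

_SK_ALIASES = {
    "a": "A",
    "archaea": "A",
    "archaeon": "A",
    "archaeal": "A",
    "b": "B",
    "bacteria": "B",
    "bacterium": "B",
    "bacterial": "B",
    "e": "E",
    "eukarya": "E",
    "eukaryota": "E",
    "eukaryote": "E",
    "eukaryotes": "E",
    "eukaryal": "E",
}

ID_PATTERNS: dict[str, re.Pattern[str]] = {
    # class letter, fold integer, superfamily integer, e.g. "c.37.1"
    "SCOP_FSF": re.compile(r"^[a-z]\.\d+\.\d+$"),
    # zero-padded 7-digit GO accession, e.g. "GO:0008658"
    "GO_TERM": re.compile(r"^GO:\d{7}$"),
    "GENERIC": re.compile(r"^\S+$"),
}


def normalize_superkingdom(label: str) -> str:
    """Map long or short, case-insensitive superkingdom labels to A/B/E."""
    key = str(label).strip().lower()
    try:
        return _SK_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown superkingdom label {label!r}; expected one of "
            "Archaea/Bacteria/Eukarya (or A/B/E)"
        ) from None


class TraitMatrix:
    """Organism x trait abundance table with a derived occurrence view.

    Parameters
    ----------
    abundance:
        DataFrame indexed by trait id with organism ids as columns; values
        must be non-negative integers.
    id_scheme:
        One of ``SCOP_FSF``, ``GO_TERM`` or ``GENERIC``; every trait id must
        match the scheme's syntax.
    """

    def __init__(self, abundance: pd.DataFrame, id_scheme: str = "GENERIC"):
        if id_scheme not in ID_PATTERNS:
            raise ConfigurationError(
                f"unknown id scheme {id_scheme!r}; expected one of {sorted(ID_PATTERNS)}"
            )
        if abundance.index.has_duplicates:
            dupes = abundance.index[abundance.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate trait ids: {dupes}")
        if abundance.columns.has_duplicates:
            dupes = abundance.columns[abundance.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate organism ids: {dupes}")
        values = abundance.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("abundance values must be integers")
        if values.size and (values < 0).any():
            raise ValidationError("abundance values must be non-negative")
        pattern = ID_PATTERNS[id_scheme]
        bad = [t for t in abundance.index.astype(str) if not pattern.match(t)]
        if bad:
            raise SchemeMismatchError(
                f"{len(bad)} trait id(s) do not match scheme {id_scheme}: "
                f"{bad[:10]}{'...' if len(bad) > 10 else ''}"
            )
        df = abundance.astype(np.int64).copy()
        df.index = df.index.astype(str)
        df.index.name = "trait_id"
        df.columns = df.columns.astype(str)
        self._abundance = df
        self.id_scheme = id_scheme

    @property
    def abundance(self) -> pd.DataFrame:
        return self._abundance

    @property
    def occurrence(self) -> pd.DataFrame:
        """Boolean presence/absence view: ``abundance >= 1``."""
        return self._abundance >= 1

    @property
    def trait_ids(self) -> list[str]:
        return list(self._abundance.index)

    @property
    def organism_ids(self) -> list[str]:
        return list(self._abundance.columns)

    @property
    def n_traits(self) -> int:
        return self._abundance.shape[0]

    @property
    def n_organisms(self) -> int:
        return self._abundance.shape[1]

    def subset(
        self,
        traits: Sequence[str] | None = None,
        organisms: Sequence[str] | None = None,
    ) -> "TraitMatrix":
        df = self._abundance
        if organisms is not None:
            df = df.loc[:, [o for o in df.columns if o in set(organisms)]]
        if traits is not None:
            keep = set(traits)
            df = df.loc[[t for t in df.index if t in keep]]
        return TraitMatrix(df, id_scheme=self.id_scheme)

    def write_tsv(self, path: str | Path) -> None:
        self._abundance.to_csv(path, sep="\t")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        return self.id_scheme == other.id_scheme and self._abundance.equals(
            other._abundance
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TraitMatrix({self.n_traits} traits x {self.n_organisms} organisms, "
            f"scheme={self.id_scheme})"
        )


@dataclass(frozen=True)
class OrganismRecord:
    """One organism's metadata: superkingdom, lifestyle and GO coverage."""

    organism_id: str
    superkingdom: str  # "A", "B" or "E"
    lifestyle: str = "unknown"
    annotation_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValidationError(
                f"organism {self.organism_id}: superkingdom must be one of "
                f"{SUPERKINGDOMS}, got {self.superkingdom!r}"
            )
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"organism {self.organism_id}: lifestyle must be one of "
                f"{LIFESTYLES}, got {self.lifestyle!r}"
            )
        cov = self.annotation_coverage
        if cov is not None and not (0.0 <= cov <= 1.0):
            raise ValidationError(
                f"organism {self.organism_id}: annotation_coverage {cov} outside [0, 1]"
            )


@dataclass(frozen=True)
class DatasetConfig:
    """Dataset-construction thresholds applied by :func:`filter_dataset`."""

    coverage_threshold: float = 0.5
    free_living_only: bool = False
    exclusion_list: frozenset[str] = frozenset()
    hgt_threshold: float = 0.6
    tail_threshold: float = 0.8
    near_universal_threshold: float = 0.90

    def __post_init__(self) -> None:
        for name in (
            "coverage_threshold",
            "hgt_threshold",
            "tail_threshold",
            "near_universal_threshold",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


@dataclass
class FilterReport:
    """Accounting of what :func:`filter_dataset` removed and why."""

    n_input_traits: int
    n_input_organisms: int
    n_organisms_failing_coverage: int
    n_organisms_not_free_living: int
    n_organisms_retained: int
    n_excluded_traits: int
    n_zero_occurrence_traits: int
    n_traits_retained: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_trait_matrix(path: str | Path, id_scheme: str = "GENERIC") -> TraitMatrix:
    """Read a tab-separated trait matrix.

    The first column header must be ``trait_id``; remaining headers are
    organism ids and every cell a base-10 non-negative integer.  Malformed
    cells raise :class:`MatrixParseError` naming the offending row and
    column; ids failing the scheme's syntax raise :class:`SchemeMismatchError`.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise MatrixParseError(f"{path}: expected a trait_id column plus organisms")
    if raw.columns[0] != "trait_id":
        raise MatrixParseError(
            f"{path}: first column header must be 'trait_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("trait_id")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad_mask = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
    if bad_mask.to_numpy().any():
        i, j = np.argwhere(bad_mask.to_numpy())[0]
        raise MatrixParseError(
            f"{path}: malformed cell at trait {raw.index[i]!r}, "
            f"organism {raw.columns[j]!r}: {raw.iat[i, j]!r} "
            "(expected a non-negative integer)"
        )
    return TraitMatrix(numeric.astype(np.int64), id_scheme=id_scheme)


_META_COLUMNS = ("organism_id", "superkingdom", "lifestyle", "annotation_coverage")


def load_organism_metadata(path: str | Path) -> list[OrganismRecord]:
    """Read a tab-separated organism metadata table.

    Required columns: organism_id, superkingdom, lifestyle,
    annotation_coverage (blank coverage cells mean "not assessed").
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if table["organism_id"].duplicated().any():
        dupes = table.loc[table["organism_id"].duplicated(), "organism_id"].tolist()
        raise ValidationError(f"{path}: duplicate organism ids {dupes}")
    records = []
    for row in table.itertuples(index=False):
        lifestyle = str(row.lifestyle).strip().lower().replace("-", "_").replace(" ", "_")
        if lifestyle in ("", "na", "none"):
            lifestyle = "unknown"
        cov_raw = str(row.annotation_coverage).strip()
        coverage = None if cov_raw == "" else float(cov_raw)
        records.append(
            OrganismRecord(
                organism_id=str(row.organism_id),
                superkingdom=normalize_superkingdom(row.superkingdom),
                lifestyle=lifestyle,
                annotation_coverage=coverage,
            )
        )
    return records


def write_organism_metadata(records: Iterable[OrganismRecord], path: str | Path) -> None:
    rows = [
        {
            "organism_id": r.organism_id,
            "superkingdom": r.superkingdom,
            "lifestyle": r.lifestyle,
            "annotation_coverage": "" if r.annotation_coverage is None else r.annotation_coverage,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_META_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_exclusion_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text exclusion list: one trait id per line, '#' comments."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            ids.add(entry)
    return frozenset(ids)


def records_by_id(records: Iterable[OrganismRecord]) -> dict[str, OrganismRecord]:
    return {r.organism_id: r for r in records}


def filter_dataset(
    matrix: TraitMatrix,
    metadata: Sequence[OrganismRecord],
    config: DatasetConfig,
) -> tuple[TraitMatrix, FilterReport]:
    """Apply the dataset-construction rules; returns the filtered matrix and
    an accounting report.

    Organism rules (coverage, lifestyle) and trait rules (exclusion list,
    zero occurrence after organism filtering) are applied in a fixed order;
    the retained-trait arithmetic
    ``retained = input - exclusion hits - zero-occurrence drops``
    is asserted on every run.  Idempotent for a fixed config.
    """
    by_id = records_by_id(metadata)
    missing = [o for o in matrix.organism_ids if o not in by_id]
    if missing:
        raise ValidationError(
            f"{len(missing)} organism(s) in matrix absent from metadata: {missing[:10]}"
        )

    n_fail_cov = 0
    n_not_free = 0
    keep_orgs = []
    for org in matrix.organism_ids:
        rec = by_id[org]
        cov = rec.annotation_coverage
        # inclusive comparison: coverage exactly at the threshold is retained;
        # absent coverage means the filter was not assessed and passes
        fails_cov = cov is not None and cov < config.coverage_threshold
        not_free = config.free_living_only and rec.lifestyle != "free_living"
        if fails_cov:
            n_fail_cov += 1
        if not_free:
            n_not_free += 1
        if not (fails_cov or not_free):
            keep_orgs.append(org)

    df = matrix.abundance.loc[:, keep_orgs]
    excluded_hits = [t for t in df.index if t in config.exclusion_list]
    df = df.drop(index=excluded_hits)
    occ_total = (df >= 1).sum(axis=1)
    zero_traits = list(occ_total.index[occ_total == 0])
    df = df.drop(index=zero_traits)

    report = FilterReport(
        n_input_traits=matrix.n_traits,
        n_input_organisms=matrix.n_organisms,
        n_organisms_failing_coverage=n_fail_cov,
        n_organisms_not_free_living=n_not_free,
        n_organisms_retained=len(keep_orgs),
        n_excluded_traits=len(excluded_hits),
        n_zero_occurrence_traits=len(zero_traits),
        n_traits_retained=df.shape[0],
    )
    assert (
        report.n_traits_retained
        == report.n_input_traits
        - report.n_excluded_traits
        - report.n_zero_occurrence_traits
    ), "trait-retention arithmetic violated"
    return TraitMatrix(df, id_scheme=matrix.id_scheme), report


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_manifest(
    config: DatasetConfig, inputs: Mapping[str, str | Path] | None = None
) -> dict:
    """Echo the applied configuration (and input digests) for provenance."""
    manifest: dict = {
        "config": {
            "coverage_threshold": config.coverage_threshold,
            "free_living_only": config.free_living_only,
            "exclusion_list_size": len(config.exclusion_list),
            "hgt_threshold": config.hgt_threshold,
            "tail_threshold": config.tail_threshold,
            "near_universal_threshold": config.near_universal_threshold,
        }
    }
    if inputs:
        manifest["inputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        }
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
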