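"""Tabular containers and delimited-text I/O for the pipeline.

All inputs and outputs are plain CSV (RFC-style quoting, so compound names
such as ``2,3-Butanedione`` and ``(E)-2-nonenal`` survive round-trips) plus
JSON sidecars. Missing intensities are encoded as *empty cells*, never as 0:
zero is a legal intensity, and the missingness filter must count true
absences. Every writer emits a schema version (a ``# schema:`` comment line
on CSVs, a ``"schema"`` key in JSON); every reader validates rather than
coerces.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "flavoromics/1"

#: Closed chemical-class vocabulary for volatile compounds.
CHEMICAL_CLASSES = (
    "hydrocarbons",
    "alcohols",
    "aldehydes",
    "esters",
    "ketones",
    "others",
)


class TableValidationError(ValueError):
    """Raised when a table violates its structural contract."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """A samples x features intensity matrix with group labels.

    Parameters
    ----------
    values
        Non-negative intensities; ``NaN`` marks a missing measurement.
        Index holds sample ids, columns hold feature ids (both unique).
    group_labels
        One group label per sample, aligned with ``values.index``.
    internal_standard_id
        Feature id of the spiked internal-standard channel, if present.
    """

    values: pd.DataFrame
    group_labels: pd.Series
    internal_standard_id: str | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate feature ids: {dups}")
        self.values = v = v.astype(float)
        neg = np.argwhere((v.to_numpy() < 0) & ~np.isnan(v.to_numpy()))
        if neg.size:
            r, c = neg[0]
            raise TableValidationError(
                f"negative intensity at sample {v.index[r]!r}, "
                f"feature {v.columns[c]!r}"
            )
        labels = pd.Series(self.group_labels)
        if len(labels) != len(v.index):
            raise TableValidationError(
                f"{len(labels)} group labels for {len(v.index)} samples"
            )
        labels.index = v.index
        self.group_labels = labels.astype(str)
        if self.internal_standard_id is not None and (
            self.internal_standard_id not in v.columns
        ):
            raise TableValidationError(
                f"internal standard {self.internal_standard_id!r} "
                "is not a feature of the table"
            )

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.group_labels))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing cells."""
        return self.values.isna().mean(axis=0)

    def subset_groups(self, groups: Sequence[str]) -> "FeatureTable":
        mask = self.group_labels.isin(list(groups))
        if not mask.any():
            raise TableValidationError(f"no samples in groups {list(groups)}")
        return replace(
            self,
            values=self.values.loc[mask].copy(),
            group_labels=self.group_labels.loc[mask].copy(),
        )

    def drop_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        keep = [c for c in self.values.columns if c not in set(feature_ids)]
        is_id = self.internal_standard_id
        if is_id is not None and is_id not in keep:
            is_id = None
        return replace(self, values=self.values[keep].copy(), internal_standard_id=is_id)


def write_feature_table(
    table: FeatureTable, path: str | Path, metadata_path: str | Path | None = None
) -> Path:
    """Write a :class:`FeatureTable` as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(".meta.json")
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        table.values.to_csv(fh, index_label="sample_id")
    meta = {
        "schema": SCHEMA_VERSION,
        "group_labels": {s: g for s, g in table.group_labels.items()},
        "internal_standard_id": table.internal_standard_id,
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_feature_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`.

    Empty cells become ``NaN`` (missing), never 0. Duplicate ids, dimension
    mismatches and negative intensities are rejected with coordinates.
    """
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(".meta.json")
    # pandas silently mangles duplicate header entries; check them first
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if row and not row[0].startswith("#"):
                header = row[1:]
                break
        else:  # pragma: no cover - empty file
            raise TableValidationError(f"{path}: no header row")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise TableValidationError(f"{path}: duplicate feature id {name!r}")
        seen.add(name)
    values = pd.read_csv(path, comment="#", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns = values.columns.astype(str)
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        warnings.warn(
            f"{path.name}: {n_missing} missing cell(s) read as NaN", stacklevel=2
        )
    with open(metadata_path) as fh:
        meta = json.load(fh)
    labels = pd.Series(meta["group_labels"], dtype=str)
    missing_samples = [s for s in values.index if s not in labels.index]
    if missing_samples:
        raise TableValidationError(
            f"{metadata_path}: no group label for samples {missing_samples}"
        )
    return FeatureTable(
        values=values,
        group_labels=labels.reindex(values.index),
        internal_standard_id=meta.get("internal_standard_id"),
    )


# ---------------------------------------------------------------------------
# VOC annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "feature_id",
    "compound_name",
    "cas",
    "chemical_class",
    "theoretical_ri",
    "odor_threshold",
    "descriptors",
]


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a VOC annotation frame indexed by feature id.

    Columns: ``compound_name``, ``cas`` (optional), ``chemical_class`` (from
    the closed taxonomy), ``theoretical_ri``, ``odor_threshold`` (> 0 where
    present; same units as relative content), ``descriptors`` (list of
    sensory-attribute strings).
    """
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate annotation feature ids: {dups}")
    bad_class = sorted(set(ann["chemical_class"].dropna()) - set(CHEMICAL_CLASSES))
    if bad_class:
        raise TableValidationError(
            f"chemical_class not in taxonomy {CHEMICAL_CLASSES}: {bad_class}"
        )
    ot = pd.to_numeric(ann["odor_threshold"], errors="raise")
    nonpos = ann.index[ot.notna() & (ot <= 0)].tolist()
    if nonpos:
        raise TableValidationError(f"odor_threshold must be > 0, offending: {nonpos}")
    ann = ann.copy()
    ann["odor_threshold"] = ot
    ann["descriptors"] = [
        list(d) if isinstance(d, (list, tuple)) else _split_descriptors(d)
        for d in ann["descriptors"]
    ]
    return ann


def _split_descriptors(raw: object) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    return [tok for tok in str(raw).split(";") if tok]


def write_annotations(ann: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = ann.copy()
    out["descriptors"] = [";".join(d) for d in out["descriptors"]]
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        out.to_csv(fh, index_label="feature_id", quoting=csv.QUOTE_MINIMAL)
    return path


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, comment="#", index_col="feature_id")
    return validate_annotations(ann)


# ---------------------------------------------------------------------------
# Peak QC records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakRecord:
    """Per-feature peak quality: S/N ratio, library-match similarity, RI."""

    feature_id: str
    signal_to_noise: float
    similarity: float
    calculated_ri: float | None = None

    def __post_init__(self) -> None:
        if self.signal_to_noise < 0:
            raise TableValidationError(
                f"{self.feature_id}: signal_to_noise must be >= 0"
            )
        if not 0 <= self.similarity <= 999:
            raise TableValidationError(
                f"{self.feature_id}: similarity must be in [0, 999]"
            )


def write_peak_records(records: Sequence[PeakRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "signal_to_noise": [r.signal_to_noise for r in records],
            "similarity": [r.similarity for r in records],
            "calculated_ri": [r.calculated_ri for r in records],
        }
    )
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        rows.to_csv(fh, index=False)
    return path


def read_peak_records(path: str | Path) -> list[PeakRecord]:
    rows = pd.read_csv(path, comment="#")
    return [
        PeakRecord(
            feature_id=str(r.feature_id),
            signal_to_noise=float(r.signal_to_noise),
            similarity=float(r.similarity),
            calculated_ri=None if pd.isna(r.calculated_ri) else float(r.calculated_ri),
        )
        for r in rows.itertuples()
    ]


# ---------------------------------------------------------------------------
# Alkane ladder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlkaneLadder:
    """n-Alkane calibration ladder for retention-index computation.

    ``carbon_numbers`` are sorted integers >= 5 (consecutive or gapped);
    ``retention_times`` (minutes) are strictly increasing.
    """

    carbon_numbers: tuple[int, ...]
    retention_times: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.carbon_numbers)
        t = np.asarray(self.retention_times, dtype=float)
        if len(c) != len(t):
            raise TableValidationError("ladder carbon/time lengths differ")
        if len(c) < 2:
            raise TableValidationError("ladder needs at least two alkanes")
        if (c < 5).any():
            raise TableValidationError("carbon numbers must be >= 5")
        if not (np.diff(c) > 0).all():
            raise TableValidationError("carbon numbers must be strictly increasing")
        if not (np.diff(t) > 0).all():
            raise TableValidationError("retention times must be strictly increasing")
        object.__setattr__(self, "carbon_numbers", tuple(int(x) for x in c))
        object.__setattr__(self, "retention_times", tuple(float(x) for x in t))

    @property
    def span(self) -> tuple[float, float]:
        return self.retention_times[0], self.retention_times[-1]


def write_ladder(ladder: AlkaneLadder, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        pd.DataFrame(
            {
                "carbon_number": ladder.carbon_numbers,
                "retention_time": ladder.retention_times,
            }
        ).to_csv(fh, index=False)
    return path


def read_ladder(path: str | Path) -> AlkaneLadder:
    rows = pd.read_csv(path, comment="#")
    return AlkaneLadder(
        carbon_numbers=tuple(int(x) for x in rows["carbon_number"]),
        retention_times=tuple(float(x) for x in rows["retention_time"]),
    )


# ---------------------------------------------------------------------------
# Pathway database
# ---------------------------------------------------------------------------


def write_pathways(pathways: Mapping[str, set[str]], path: str | Path) -> Path:
    """Write a pathway-membership map as a long-format CSV."""
    path = Path(path)
    rows = [
        {"pathway_id": pw, "feature_id": f}
        for pw in sorted(pathways)
        for f in sorted(pathways[pw])
    ]
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        pd.DataFrame(rows, columns=["pathway_id", "feature_id"]).to_csv(fh, index=False)
    return path


def read_pathways(
    path: str | Path, known_features: set[str] | None = None
) -> dict[str, set[str]]:
    """Read pathway membership; unknown feature ids warn but are kept.

    The analysis universe is declared separately at test time, so membership
    of features outside ``known_features`` is informational, not fatal.
    """
    rows = pd.read_csv(path, comment="#")
    db: dict[str, set[str]] = {}
    for r in rows.itertuples():
        db.setdefault(str(r.pathway_id), set()).add(str(r.feature_id))
    if known_features is not None:
        unknown = sorted(
            {f for members in db.values() for f in members} - known_features
        )
        if unknown:
            warnings.warn(
                f"{Path(path).name}: {len(unknown)} pathway member(s) not among "
                f"known features (kept): {unknown[:5]}...",
                stacklevel=2,
            )
    return db
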