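"""Data model for multimodal clinical records with missing features and labels.

A cohort is a flat table of subject-visits.  Each feature is declared in a
JSON schema as numerical, categorical, or a fixed-length imaging-embedding
vector.  Diagnostic labels form a fixed 13-entry taxonomy: three cognitive
statuses (NC, MCI, DE) and ten dementia etiologies.  Both features and labels
may be missing; missingness is encoded as cell emptiness in the table, never
as a sentinel value, so legitimate zeros survive round trips.

Labels carry three states through a pair of vectors: ``y`` (0/1) and
``label_mask`` (1 = ascertained, 0 = missing).  Entries with ``label_mask``
zero are contractually ignored by every downstream computation, which lets
loss masking be a pure multiply.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed label order; defines index i in every loss formula.
LABELS: tuple[str, ...] = (
    "NC", "MCI", "DE",
    "AD", "LBD", "VD", "PRD", "FTD", "NPH", "SEF", "PSY", "TBI", "ODE",
)
COGNITIVE_LABELS: tuple[str, ...] = LABELS[:3]
ETIOLOGY_LABELS: tuple[str, ...] = LABELS[3:]


class SchemaError(ValueError):
    """A table column or value contradicts the declared schema."""


class CodingError(SchemaError):
    """A categorical value falls outside its declared category codes."""


class IntegrityError(ValueError):
    """Duplicate (subject, visit) pairs or inconsistent record content."""


class UndefinedPrevalenceError(ValueError):
    """A label is never observed, so its prevalence is undefined."""


@dataclass(frozen=True)
class LabelTaxonomy:
    """Ordered list of the 13 diagnostic codes."""

    labels: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 13:
            raise ValueError(f"taxonomy must have 13 labels, got {len(self.labels)}")
        if len(set(self.labels)) != 13:
            raise ValueError("taxonomy labels must be unique")

    def __len__(self) -> int:
        return 13

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single feature's modality and coding."""

    name: str
    kind: str  # numerical | categorical | imaging_embedding
    categories: tuple[str, ...] = ()
    embed_dim: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("numerical", "categorical", "imaging_embedding"):
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.categories) < 2:
            raise SchemaError(f"categorical feature {self.name!r} needs >= 2 categories")
        if self.kind == "imaging_embedding" and self.embed_dim <= 0:
            raise SchemaError(f"imaging feature {self.name!r} needs embed_dim > 0")


class FeatureSchema:
    """Ordered collection of FeatureSpec; order defines token order."""

    def __init__(self, specs: Iterable[FeatureSpec]):
        self.specs: list[FeatureSpec] = list(specs)
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique within a schema")
        self._by_name = {s.name: s for s in self.specs}

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def features_of_kind(self, kind: str) -> list[FeatureSpec]:
        return [s for s in self.specs if s.kind == kind]

    # -- JSON serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": s.name,
                "kind": s.kind,
                **({"categories": list(s.categories)} if s.kind == "categorical" else {}),
                **({"embed_dim": s.embed_dim} if s.kind == "imaging_embedding" else {}),
            }
            for s in self.specs
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        specs = [
            FeatureSpec(
                name=item["name"],
                kind=item["kind"],
                categories=tuple(item.get("categories", ())),
                embed_dim=int(item.get("embed_dim", 0)),
            )
            for item in payload
        ]
        return cls(specs)

    def content_hash(self) -> str:
        import hashlib

        blob = json.dumps(
            [(s.name, s.kind, s.categories, s.embed_dim) for s in self.specs]
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Record:
    """One subject-visit: feature values, observed flags, and masked labels."""

    subject_id: str
    visit_id: str
    values: dict
    observed: dict
    y: np.ndarray  # 13-vector over {0, 1}
    label_mask: np.ndarray  # 13-vector, 1 = ascertained
    cohort: str = ""

    def validate(self, schema: FeatureSchema) -> None:
        for key in self.values:
            if key not in schema:
                raise SchemaError(f"unknown feature {key!r} in record {self.subject_id}")
        for key in self.observed:
            if key not in schema:
                raise SchemaError(f"unknown feature {key!r} in record {self.subject_id}")
        if len(self.y) != 13 or len(self.label_mask) != 13:
            raise IntegrityError("label vectors must have length 13")


@dataclass
class Cohort:
    """A schema, a taxonomy, and a list of validated records."""

    schema: FeatureSchema
    records: list[Record]
    taxonomy: LabelTaxonomy = field(default_factory=LabelTaxonomy)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.subject_id, r.visit_id)
            if key in seen:
                raise IntegrityError(f"duplicate (subject, visit) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def Y(self) -> np.ndarray:
        """(n, 13) label matrix."""
        return np.array([r.y for r in self.records], dtype=float)

    @property
    def M(self) -> np.ndarray:
        """(n, 13) label-mask matrix."""
        return np.array([r.label_mask for r in self.records], dtype=float)

    def subjects(self) -> list[str]:
        out, seen = [], set()
        for r in self.records:
            if r.subject_id not in seen:
                seen.add(r.subject_id)
                out.append(r.subject_id)
        return out


# ---------------------------------------------------------------------------
# Table I/O


def _is_missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    if isinstance(cell, str) and cell.strip() == "":
        return True
    return False


def read_cohort(
    table_path: str | Path,
    schema_path: str | Path,
    embeddings_path: str | Path | None = None,
    taxonomy: LabelTaxonomy | None = None,
) -> Cohort:
    """Read a cohort from a CSV/TSV feature table plus a JSON schema.

    Empty cells denote missing features; label columns admit {0, 1, empty},
    empty meaning the label was never ascertained for that record.  Imaging
    embedding vectors live in a companion table keyed by
    (subject_id, visit_id, feature) with columns ``e0..e{d-1}``.
    """
    schema = FeatureSchema.from_json(schema_path)
    taxonomy = taxonomy or LabelTaxonomy()
    table_path = Path(table_path)
    sep = "\t" if table_path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(table_path, sep=sep, dtype=str, keep_default_na=False)

    required = {"subject_id", "visit_id"}
    if not required <= set(df.columns):
        raise SchemaError("table must have subject_id and visit_id columns")

    known = set(schema.names) | set(taxonomy.labels) | {"subject_id", "visit_id", "cohort"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown feature column(s): {unknown}")

    emb_lookup: dict[tuple[str, str, str], np.ndarray] = {}
    if embeddings_path is not None:
        emb = pd.read_csv(embeddings_path)
        vec_cols = [c for c in emb.columns if c.startswith("e")]
        for _, row in emb.iterrows():
            key = (str(row["subject_id"]), str(row["visit_id"]), str(row["feature"]))
            emb_lookup[key] = row[vec_cols].to_numpy(dtype=float)

    records: list[Record] = []
    for _, row in df.iterrows():
        sid, vid = str(row["subject_id"]), str(row["visit_id"])
        values: dict = {}
        observed: dict = {}
        for spec in schema:
            if spec.name not in df.columns:
                observed[spec.name] = False
                continue
            cell = row[spec.name]
            if _is_missing(cell):
                observed[spec.name] = False
                continue
            if spec.kind == "numerical":
                values[spec.name] = float(cell)
            elif spec.kind == "categorical":
                code = str(cell)
                if code not in spec.categories:
                    raise CodingError(
                        f"feature {spec.name!r}: value {code!r} not in declared categories"
                    )
                values[spec.name] = code
            else:  # imaging_embedding: cell holds a reference flag; vector in companion
                vec = emb_lookup.get((sid, vid, spec.name))
                if vec is None:
                    observed[spec.name] = False
                    continue
                if len(vec) != spec.embed_dim:
                    raise SchemaError(
                        f"embedding for {spec.name!r} has length {len(vec)}, "
                        f"expected {spec.embed_dim}"
                    )
                values[spec.name] = vec
            observed[spec.name] = True

        y = np.zeros(13)
        mask = np.zeros(13)
        for i, lab in enumerate(taxonomy.labels):
            if lab in df.columns and not _is_missing(row[lab]):
                val = int(float(row[lab]))
                if val not in (0, 1):
                    raise SchemaError(f"label {lab} must be 0/1/empty, got {row[lab]!r}")
                y[i] = val
                mask[i] = 1.0
        records.append(
            Record(
                subject_id=sid,
                visit_id=vid,
                values=values,
                observed=observed,
                y=y,
                label_mask=mask,
                cohort=str(row["cohort"]) if "cohort" in df.columns else "",
            )
        )
    cohort = Cohort(schema=schema, records=records, taxonomy=taxonomy)
    for r in records:
        r.validate(schema)
    return cohort


def write_cohort(
    cohort: Cohort,
    table_path: str | Path,
    schema_path: str | Path | None = None,
    embeddings_path: str | Path | None = None,
) -> None:
    """Write a cohort as CSV (empty cell = missing) plus optional schema JSON."""
    rows = []
    emb_rows = []
    for r in cohort.records:
        row: dict = {"subject_id": r.subject_id, "visit_id": r.visit_id, "cohort": r.cohort}
        for spec in cohort.schema:
            if not r.observed.get(spec.name, False):
                row[spec.name] = ""
            elif spec.kind == "imaging_embedding":
                row[spec.name] = "1"  # presence flag; vector in companion table
                vec = np.asarray(r.values[spec.name], dtype=float)
                emb_rows.append(
                    {
                        "subject_id": r.subject_id,
                        "visit_id": r.visit_id,
                        "feature": spec.name,
                        **{f"e{i}": v for i, v in enumerate(vec)},
                    }
                )
            else:
                row[spec.name] = r.values[spec.name]
        for i, lab in enumerate(cohort.taxonomy.labels):
            row[lab] = "" if r.label_mask[i] == 0 else int(r.y[i])
        rows.append(row)
    table_path = Path(table_path)
    sep = "\t" if table_path.suffix in (".tsv", ".tab") else ","
    pd.DataFrame(rows).to_csv(table_path, sep=sep, index=False)
    if schema_path is not None:
        cohort.schema.to_json(schema_path)
    if emb_rows and embeddings_path is not None:
        pd.DataFrame(emb_rows).to_csv(embeddings_path, index=False)


def compute_prevalence(cohort: Cohort) -> np.ndarray:
    """Per-label fraction of positives among label-observed records.

    f_i = #(y_i = 1 and observed) / #(observed); masked entries are excluded
    by definition.  Raises if a label is never observed.
    """
    Y, M = cohort.Y, cohort.M
    n_obs = M.sum(axis=0)
    for i, lab in enumerate(cohort.taxonomy.labels):
        if n_obs[i] == 0:
            raise UndefinedPrevalenceError(f"label {lab} is never observed in this cohort")
    return (Y * M).sum(axis=0) / n_obs
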