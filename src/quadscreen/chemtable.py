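"""Domain types and readers/writers for compound/endpoint tables.

The central containers of the pipeline:

* :class:`CompoundRecord` — a curated molecule (id + canonical SMILES).
* :class:`ConditionProfile` — a hashable, ordered tuple of experimental
  condition values (buffer, gene sequence, assay, cell line, exposure
  time, ligand:G4 ratio, ...), declared per model by a
  :class:`ConditionSchema`.
* :class:`EndpointRecord` — compound × condition × continuous endpoint
  value × binary class.
* :class:`Dataset` — compounds + endpoint records + schema.

Tables travel as delimited text (comma/tab autodetected); compound
libraries as SMILES lists or SDF; screening outputs as delimited text or
an XLSX workbook with one sheet per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

from .labmath import label_endpoint

# RDKit is chatty about malformed SMILES; input validation reports
# verdicts instead, so parse errors are expected and silenced.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "SchemaError",
    "ConditionSchema",
    "ConditionProfile",
    "CompoundRecord",
    "EndpointRecord",
    "Dataset",
    "read_dataset",
    "dataset_from_frame",
    "dataset_to_frame",
    "write_dataset",
    "write_prediction_matrix",
    "validate_input_structures",
    "read_compound_library",
]


class SchemaError(ValueError):
    """An input table does not match the declared condition schema."""


@dataclass(frozen=True)
class ConditionSchema:
    """Declared shape of a model's experimental conditions.

    ``fields`` is the ordered tuple of condition-field names; ``endpoint``
    names the endpoint column ("Kd", "dTm", "IC50" or "selectivity").
    ``vocabulary`` optionally restricts a field to an allowed value list.
    Numeric condition fields (exposure time, ligand:G4 ratio) are treated
    as discrete categorical levels.
    """

    name: str
    fields: tuple
    endpoint: str
    vocabulary: Mapping[str, tuple] | None = None

    def __post_init__(self):
        object.__setattr__(self, "fields", tuple(self.fields))

    def check_value(self, field_name: str, value) -> None:
        if self.vocabulary and field_name in self.vocabulary:
            if value not in self.vocabulary[field_name]:
                raise SchemaError(
                    f"value {value!r} not in vocabulary of field {field_name!r}"
                )


@dataclass(frozen=True)
class ConditionProfile:
    """Ordered, hashable tuple of condition values keyed by field name."""

    fields: tuple
    values: tuple

    def __post_init__(self):
        object.__setattr__(self, "fields", tuple(self.fields))
        object.__setattr__(self, "values", tuple(self.values))
        if len(self.fields) != len(self.values):
            raise ValueError("fields and values must have equal length")

    @classmethod
    def from_mapping(cls, schema: ConditionSchema, mapping: Mapping) -> "ConditionProfile":
        values = []
        for f in schema.fields:
            if f not in mapping:
                raise SchemaError(f"condition field {f!r} missing")
            schema.check_value(f, mapping[f])
            values.append(mapping[f])
        return cls(schema.fields, tuple(values))

    def __getitem__(self, field_name: str):
        try:
            return self.values[self.fields.index(field_name)]
        except ValueError:
            raise KeyError(field_name) from None

    def as_dict(self) -> dict:
        return dict(zip(self.fields, self.values))


@dataclass(frozen=True)
class CompoundRecord:
    """A molecule with an opaque id and a (curated) SMILES string."""

    id: str
    smiles: str
    provenance: str = ""


@dataclass
class EndpointRecord:
    """One measured datapoint: compound × condition × endpoint value.

    ``class_label`` is 1/0 once set and must equal the threshold labeling
    of ``value`` for numeric endpoints; ``None`` marks an unset label or a
    missing endpoint value awaiting curation.
    """

    record_id: str
    compound_id: str
    condition: ConditionProfile
    endpoint_name: str
    value: object  # float, str (selectivity verdict) or None (missing)
    class_label: int | None = None

    def with_label(self) -> "EndpointRecord":
        if self.value is None:
            raise ValueError(f"record {self.record_id}: cannot label missing endpoint")
        return replace(self, class_label=label_endpoint(self.endpoint_name, self.value))


@dataclass
class Dataset:
    """Compounds, endpoint records and the schema they conform to."""

    compounds: dict  # id -> CompoundRecord
    records: list  # of EndpointRecord
    schema: ConditionSchema

    def __post_init__(self):
        for r in self.records:
            if r.compound_id not in self.compounds:
                raise ValueError(f"record {r.record_id}: unknown compound {r.compound_id}")

    def __len__(self) -> int:
        return len(self.records)

    def labeled(self) -> "Dataset":
        """Return a copy with class labels assigned from endpoint values."""
        return Dataset(
            dict(self.compounds),
            [r.with_label() for r in self.records],
            self.schema,
        )

    def subset(self, record_ids: Iterable[str]) -> "Dataset":
        wanted = set(record_ids)
        recs = [r for r in self.records if r.record_id in wanted]
        comps = {r.compound_id: self.compounds[r.compound_id] for r in recs}
        return Dataset(comps, recs, self.schema)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_endpoint(schema: ConditionSchema, raw):
    """Return (value, reject_reason).  Empty cells become None (missing)."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, None
    s = str(raw).strip()
    if s == "":
        return None, None
    if schema.endpoint == "selectivity":
        return s, None
    try:
        return float(s), None
    except ValueError:
        return None, f"unparseable endpoint value {s!r}"


def dataset_from_frame(
    frame: pd.DataFrame,
    schema: ConditionSchema,
    smiles_col: str = "smiles",
    id_col: str | None = None,
):
    """Build a :class:`Dataset` from an in-memory table.

    Returns ``(dataset, rejects)`` where ``rejects`` is a list of
    ``(row_index, reason)`` for malformed rows.  Rows with an empty
    endpoint cell are kept with ``value=None`` (flagged missing-endpoint
    for downstream curation), not rejected.
    """
    required = [smiles_col, *schema.fields, schema.endpoint]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    compounds: dict = {}
    records: list = []
    rejects: list = []
    for pos, (idx, row) in enumerate(frame.iterrows()):
        smi = row[smiles_col]
        if smi is None or (isinstance(smi, float) and pd.isna(smi)) or str(smi).strip() == "":
            rejects.append((idx, "empty smiles"))
            continue
        smi = str(smi).strip()
        try:
            profile = ConditionProfile.from_mapping(schema, row)
        except SchemaError as exc:
            rejects.append((idx, str(exc)))
            continue
        value, reason = _parse_endpoint(schema, row[schema.endpoint])
        if reason is not None:
            rejects.append((idx, reason))
            continue
        cid = str(row[id_col]) if id_col and id_col in frame.columns else f"C{pos:05d}"
        if cid not in compounds:
            compounds[cid] = CompoundRecord(id=cid, smiles=smi)
        records.append(
            EndpointRecord(
                record_id=f"R{pos:05d}",
                compound_id=cid,
                condition=profile,
                endpoint_name=schema.endpoint,
                value=value,
            )
        )
    return Dataset(compounds, records, schema), rejects


def read_dataset(
    path,
    schema: ConditionSchema,
    smiles_col: str = "smiles",
    id_col: str | None = None,
):
    """Read a delimited-text table (comma/tab autodetected) into a Dataset.

    Returns ``(dataset, rejects)``.  Malformed rows are collected in the
    rejects report, never silently dropped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    return dataset_from_frame(frame, schema, smiles_col=smiles_col, id_col=id_col)


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    for r in dataset.records:
        row = {
            "record_id": r.record_id,
            "compound_id": r.compound_id,
            "smiles": dataset.compounds[r.compound_id].smiles,
        }
        row.update(r.condition.as_dict())
        row[r.endpoint_name] = r.value
        if r.class_label is not None:
            row["class"] = r.class_label
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(dataset: Dataset, path, sep: str = ",") -> None:
    dataset_to_frame(dataset).to_csv(path, sep=sep, index=False)


def write_prediction_matrix(matrix: pd.DataFrame, path, format: str = "delimited") -> None:
    """Write a screening prediction matrix to disk.

    ``delimited`` writes one flat CSV; ``workbook`` writes an XLSX file
    with one sheet per model.  One row per (compound, condition) with
    SMILES, all condition fields, the predicted class and the AD flag.
    """
    if matrix is None or len(matrix) == 0:
        raise ValueError("prediction matrix is empty")
    path = Path(path)
    if format == "delimited":
        matrix.to_csv(path, index=False)
    elif format == "workbook":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            if "model" in matrix.columns:
                for model_name, chunk in matrix.groupby("model", sort=False):
                    chunk = chunk.dropna(axis=1, how="all")
                    chunk.to_excel(writer, sheet_name=str(model_name)[:31], index=False)
            else:
                matrix.to_excel(writer, sheet_name="predictions", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Structure validation
# ---------------------------------------------------------------------------

_ORGANIC_SUBSET = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}


def _has_carbon(mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def validate_input_structures(smiles_list: Sequence, max_heavy_atoms: int = 150) -> list:
    """Per-item verdicts for raw structure input, aligned 1:1 with input.

    Verdicts: ``ok``, ``disconnected`` (a salt/solvent adduct: exactly one
    organic fragment), ``mixture`` (two or more organic fragments),
    ``too_large`` (heavy-atom count above ``max_heavy_atoms``) or
    ``unparseable``.  Never raises, whatever the input bytes.
    """
    verdicts = []
    for item in smiles_list:
        try:
            if isinstance(item, bytes):
                item = item.decode("latin-1")
            if not isinstance(item, str) or item.strip() == "":
                verdicts.append("unparseable")
                continue
            mol = Chem.MolFromSmiles(item.strip())
            if mol is None:
                verdicts.append("unparseable")
                continue
            frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
            if len(frags) > 1:
                n_organic = sum(1 for f in frags if _has_carbon(f))
                verdicts.append("mixture" if n_organic >= 2 else "disconnected")
                continue
            if mol.GetNumHeavyAtoms() > max_heavy_atoms:
                verdicts.append("too_large")
                continue
            verdicts.append("ok")
        except Exception:  # defensive: verdicts encode failures
            verdicts.append("unparseable")
    return verdicts


def read_compound_library(path, id_prefix: str = "L") -> list:
    """Read a compound library from a SMILES list (.smi/.txt) or SDF.

    SMILES files hold one structure per line, optionally followed by an
    identifier.  Returns a list of :class:`CompoundRecord` (raw, uncurated).
    """
    path = Path(path)
    records: list = []
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            records.append(
                CompoundRecord(
                    id=name or f"{id_prefix}{i:06d}",
                    smiles=Chem.MolToSmiles(mol),
                    provenance=str(path),
                )
            )
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                cid = parts[1] if len(parts) > 1 else f"{id_prefix}{i:06d}"
                records.append(CompoundRecord(id=cid, smiles=parts[0], provenance=str(path)))
    return records
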