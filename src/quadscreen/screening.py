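"""Virtual-screening funnel: Lipinski filter → condition grids → consensus.

A compound library is filtered for drug-likeness (Lipinski's rule of 5),
then every surviving compound is evaluated by each endpoint model over an
enumerated grid of experimental conditions (sequences × buffers × assays
× ligand:G4 ratios, or cell lines × exposure times × assays), producing a
prediction matrix with one row per (compound, condition) carrying the
predicted class and the applicability-domain verdict.  A consensus rule
then retains compounds predicted positive in all models — positivity per
model being satisfiable by any condition row (default) or required of
every condition row.

Condition vocabularies live in a versioned JSON config; the bundled
default lists the grids most abundant in typical G4 modeling data.  The
oncogene/target field is derived from the gene sequence by lookup, not
enumerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chemtable import ConditionProfile
from .descriptors import compute_descriptors, maccs_fingerprints
from .applicability import ad_verdict
from .multitask import modified_column

__all__ = [
    "MODEL_NAMES",
    "load_condition_config",
    "ConditionGrid",
    "enumerate_conditions",
    "lipinski_filter",
    "screen",
    "consensus_positive",
]

MODEL_NAMES = ("selectivity", "interaction", "stabilization", "cytotoxicity")


def load_condition_config(path=None) -> dict:
    """Load a condition-grid config; the bundled default without a path."""
    if path is None:
        text = resources.files("quadscreen.data").joinpath("default_conditions.json").read_text()
    else:
        text = open(path).read()
    return json.loads(text)


@dataclass
class ConditionGrid:
    """Per-model condition axes and their cartesian-product enumerator."""

    model: str
    fields: tuple
    axes: dict  # field -> list of values, in config order
    derived: dict = dc_field(default_factory=dict)  # derived field -> source field
    lookup: dict = dc_field(default_factory=dict)  # source value -> derived value

    @classmethod
    def from_config(cls, model_name: str, config: dict | None = None) -> "ConditionGrid":
        config = config or load_condition_config()
        try:
            spec = config["models"][model_name]
        except KeyError:
            raise KeyError(f"no grid for model {model_name!r} in config") from None
        fields = tuple(spec["fields"])
        axes = {f: list(spec["grid"][f]) for f in fields}
        missing = [f for f in spec["grid"] if f not in fields]
        if missing:
            raise ValueError(f"grid field(s) {missing} not in model schema")
        return cls(
            model=model_name,
            fields=fields,
            axes=axes,
            derived=dict(spec.get("derived") or {}),
            lookup=dict(config.get("targets") or {}),
        )

    @property
    def size(self) -> int:
        out = 1
        for f in self.fields:
            out *= len(self.axes[f])
        return out

    def enumerate(self) -> list:
        """All condition profiles, fields in schema order, values in
        config order; derived fields appended via the lookup."""
        profiles = []
        derived_fields = tuple(self.derived)
        all_fields = self.fields + derived_fields
        for combo in product(*(self.axes[f] for f in self.fields)):
            values = list(combo)
            for dfield in derived_fields:
                source = self.derived[dfield]
                values.append(self.lookup.get(combo[self.fields.index(source)]))
            profiles.append(ConditionProfile(all_fields, tuple(values)))
        return profiles


def enumerate_conditions(model_name: str, grid: ConditionGrid | None = None, config: dict | None = None) -> list:
    """Deterministic condition enumeration for one model."""
    grid = grid or ConditionGrid.from_config(model_name, config)
    return grid.enumerate()


# ---------------------------------------------------------------------------
# Lipinski filter
# ---------------------------------------------------------------------------

_RO5_RULES = (
    ("MW>500", lambda m: Descriptors.MolWt(m) > 500),
    ("logP>5", lambda m: Crippen.MolLogP(m) > 5),
    ("HBD>5", lambda m: rdMolDescriptors.CalcNumHBD(m) > 5),
    ("HBA>10", lambda m: rdMolDescriptors.CalcNumHBA(m) > 10),
)


def lipinski_filter(compounds, max_violations: int = 0):
    """Rule-of-5 drug-likeness filter.

    Pass iff MW <= 500, logP <= 5, H-bond donors <= 5 and acceptors <= 10
    (strict by default; ``max_violations=1`` allows the conventional
    single violation).  Returns ``(passed, failed)`` where ``failed``
    pairs each compound with its violated rules.  Unparseable structures
    fail with rule "unparseable" — validate input upstream.
    """
    passed, failed = [], []
    for c in compounds:
        mol = Chem.MolFromSmiles(c.smiles)
        if mol is None:
            failed.append((c, ["unparseable"]))
            continue
        violations = [name for name, pred in _RO5_RULES if pred(mol)]
        if len(violations) <= max_violations:
            passed.append(c)
        else:
            failed.append((c, violations))
    return passed, failed


# ---------------------------------------------------------------------------
# Screening engine
# ---------------------------------------------------------------------------

def _screen_one_model(name, model, profiles, compounds, desc, fps):
    means = model.condition_means
    if means is None:
        raise ValueError(f"model {name!r} has no ConditionMeans; cannot screen")
    desc_sub = desc[list(means.descriptors)]
    rows = []
    for comp in compounds:
        xi = desc_sub.loc[comp.id].to_numpy(dtype=float)
        fp = fps.loc[comp.id].to_numpy(dtype=float)
        comp_failed = bool(np.isnan(xi).any())
        for profile in profiles:
            row = {"model": name, "compound_id": comp.id, "smiles": comp.smiles}
            row.update(profile.as_dict())
            if comp_failed:
                row.update({"prediction": pd.NA, "in_ad": False, "note": "missing descriptors"})
                rows.append(row)
                continue
            deltas = {}
            unseen = None
            for f in means.fields:
                mu = means.means[f].get(profile[f])
                if mu is None:
                    unseen = f
                    break
                for d, val in zip(means.descriptors, xi - mu):
                    deltas[modified_column(d, f)] = val
            if unseen is not None:
                row.update({"prediction": pd.NA, "in_ad": False,
                            "note": f"unseen category for field {unseen!r}"})
                rows.append(row)
                continue
            x = pd.DataFrame([[deltas[c] for c in model.columns]], columns=list(model.columns))
            pred = int(model.predict(x)[0])
            row["prediction"] = pred
            if model.ad_reference is not None:
                verdict = ad_verdict(fp, x.iloc[0].to_numpy(), model.ad_reference)
                row.update(
                    {
                        "in_ad": verdict.inside,
                        "ad_similarity": verdict.similarity,
                        "ad_euclidean": verdict.euclidean,
                        "ad_leverage": verdict.leverage,
                    }
                )
            else:
                row["in_ad"] = pd.NA
            rows.append(row)
    return rows


def screen(
    compounds,
    models: dict,
    grids: dict | None = None,
    descriptor_matrix: pd.DataFrame | None = None,
    config: dict | None = None,
) -> pd.DataFrame:
    """Predict every compound over every model's condition grid.

    ``models`` maps model name -> fitted :class:`ClassifierModel` (with
    condition means and AD reference attached); ``grids`` optionally maps
    model name -> :class:`ConditionGrid` (default grids from the config
    otherwise).  Descriptors are computed once per compound with the
    builtin backend unless a matching precomputed matrix is supplied; a
    backend mismatch against any model is refused.  Per-compound
    failures are isolated into rows with a missing prediction.

    Predictions are reported for every row, inside the AD or not; the AD
    flag tells the reader which ones to trust.
    """
    compounds = list(compounds)
    if descriptor_matrix is None:
        descriptor_matrix = compute_descriptors(compounds, backend="builtin")
    backend = descriptor_matrix.attrs.get("backend")
    for name, model in models.items():
        if model.backend is not None and model.backend != backend:
            raise ValueError(
                f"descriptor backend mismatch for model {name!r}: "
                f"model trained on {model.backend!r}, matrix from {backend!r}"
            )
    fps = maccs_fingerprints(compounds)

    all_rows = []
    for name, model in models.items():
        if grids and name in grids:
            profiles = grids[name].enumerate()
        else:
            profiles = enumerate_conditions(name, config=config)
        all_rows.extend(
            _screen_one_model(name, model, profiles, compounds, descriptor_matrix, fps)
        )
    return pd.DataFrame(all_rows)


def consensus_positive(matrix: pd.DataFrame, rule: str = "any_condition", required_models=None) -> list:
    """Compounds predicted positive in all (required) models.

    ``any_condition`` (default): a compound passes a model if at least
    one of its condition rows is predicted positive; ``all_conditions``:
    every row must be positive.  The ``all_conditions`` pass-list is
    always a subset of the ``any_condition`` one.
    """
    if rule not in ("any_condition", "all_conditions"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    required = tuple(required_models) if required_models is not None else MODEL_NAMES
    present = set(matrix["model"].unique())
    missing = [m for m in required if m not in present]
    if missing:
        raise ValueError(f"prediction matrix missing model(s): {missing}")

    out = []
    for cid, chunk in matrix.groupby("compound_id", sort=False):
        ok = True
        for m in required:
            preds = chunk.loc[chunk["model"] == m, "prediction"]
            if len(preds) == 0:
                ok = False
                break
            pos = (preds.fillna(0).astype(int) == 1)
            ok = pos.any() if rule == "any_condition" else pos.all()
            if not ok:
                break
        if ok:
            out.append(cid)
    return out
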