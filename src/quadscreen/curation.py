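"""Chemical-structure curation and two-stage biological duplicate analysis.

Chemical curation: parse/repair check, salt and solvent stripping (largest
organic fragment kept), removal of purely inorganic or organometallic
species, charge standardization and canonical-tautomer normalization to a
canonical SMILES.  An explicit-hydrogen flag is recorded for descriptor
backends that want H-complete graphs.

Biological curation: records with missing endpoints are dropped; then

* duplicate analysis I collapses groups identical in (canonical structure,
  full condition profile, endpoint value) to a single record;
* duplicate analysis II handles groups identical in (structure, condition)
  but with differing values: if the value range is below ``diff_cutoff``
  (default 0.5 on the endpoint's native scale) the group is averaged; if
  all values still map to the same activity class, the record closest to
  the group median is kept; class-conflicting groups are removed entirely.

Activity-cliff analysis is deliberately not performed: with strongly
condition-dependent endpoints, apparent cliffs are usually condition
artifacts rather than data errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chemtable import CompoundRecord, Dataset
from .labmath import label_endpoint

logger = logging.getLogger(__name__)

__all__ = [
    "CurationReport",
    "standardize_structure",
    "curate_chemistry",
    "drop_missing_endpoints",
    "duplicate_analysis_I",
    "duplicate_analysis_II",
    "curate",
]

_ORGANIC_SUBSET = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}

_ACTIONS = (
    "fixed",
    "normalized",
    "removed_unparseable",
    "removed_inorganic",
    "removed_missing_endpoint",
    "merged_dupI",
    "averaged_dupII",
    "kept_same_class_dupII",
    "removed_conflicting",
)


@dataclass
class CurationReport:
    """Bookkeeping for one or more curation steps.

    ``counts`` tallies actions; ``audit`` holds (record-or-compound id,
    action, detail) triples; the balance invariant
    input = output + removals + merge-collapsed always holds for the
    full chain.
    """

    counts: dict = dc_field(default_factory=lambda: {a: 0 for a in _ACTIONS})
    audit: list = dc_field(default_factory=list)
    explicit_hydrogens_recorded: bool = True

    def log(self, ident: str, action: str, detail: str = "") -> None:
        self.counts[action] = self.counts.get(action, 0) + 1
        self.audit.append((ident, action, detail))

    def merge(self, other: "CurationReport") -> "CurationReport":
        for k, v in other.counts.items():
            self.counts[k] = self.counts.get(k, 0) + v
        self.audit.extend(other.audit)
        return self

    def removed(self) -> int:
        return sum(
            v for k, v in self.counts.items() if k.startswith("removed_")
        )

    def collapsed(self) -> int:
        return (
            self.counts.get("merged_dupI", 0)
            + self.counts.get("averaged_dupII", 0)
            + self.counts.get("kept_same_class_dupII", 0)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.audit, columns=["id", "action", "detail"])


# ---------------------------------------------------------------------------
# Chemical curation
# ---------------------------------------------------------------------------

_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()
_tautomerizer = rdMolStandardize.TautomerEnumerator()


def standardize_structure(smiles: str):
    """Standardize one structure.  Returns (canonical_smiles, actions) or
    (None, reason) when the structure is unsalvageable.

    Pipeline: parse → cleanup → keep largest organic fragment → reject
    carbon-free or metal-containing species → neutralize charges →
    canonical tautomer → canonical SMILES.
    """
    actions = []
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, "unparseable"
    try:
        mol = rdMolStandardize.Cleanup(mol)
        n_frags = len(Chem.GetMolFrags(mol))
        if n_frags > 1:
            mol = _fragment_chooser.choose(mol)
            actions.append("salt_stripped")
        if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
            return None, "inorganic"
        if any(a.GetAtomicNum() not in _ORGANIC_SUBSET for a in mol.GetAtoms()):
            return None, "organometallic"
        mol = _uncharger.uncharge(mol)
        mol = _tautomerizer.Canonicalize(mol)
        canonical = Chem.MolToSmiles(mol)
    except Exception as exc:  # RDKit sanitization failures
        return None, f"standardization failed: {exc}"
    if canonical != smiles:
        actions.append("normalized")
    return canonical, actions


def curate_chemistry(compounds):
    """Standardize a list of :class:`CompoundRecord`.

    Unsalvageable structures are removed with a reason in the report, not
    raised.  Idempotent: already-canonical input passes through unchanged
    with zero counts.
    """
    report = CurationReport()
    out = []
    for rec in compounds:
        canonical, info = standardize_structure(rec.smiles)
        if canonical is None:
            action = (
                "removed_inorganic"
                if info in ("inorganic", "organometallic")
                else "removed_unparseable"
            )
            report.log(rec.id, action, info)
            continue
        if "salt_stripped" in info:
            report.log(rec.id, "fixed", "salt/solvent fragment stripped")
        if "normalized" in info:
            report.log(rec.id, "normalized", f"{rec.smiles} -> {canonical}")
        out.append(CompoundRecord(id=rec.id, smiles=canonical, provenance=rec.provenance))
    return out, report


# ---------------------------------------------------------------------------
# Biological curation
# ---------------------------------------------------------------------------

def drop_missing_endpoints(dataset: Dataset):
    """Remove records whose endpoint value is unset; counts logged."""
    report = CurationReport()
    kept = []
    for r in dataset.records:
        if r.value is None:
            report.log(r.record_id, "removed_missing_endpoint")
        else:
            kept.append(r)
    if not kept and dataset.records:
        warnings.warn("all records had missing endpoints; dataset is empty")
    comps = {r.compound_id: dataset.compounds[r.compound_id] for r in kept}
    return Dataset(comps, kept, dataset.schema), report


def _group_key(dataset: Dataset, record):
    return (dataset.compounds[record.compound_id].smiles, record.condition)


def duplicate_analysis_I(dataset: Dataset):
    """Collapse records identical in (structure, conditions, value)."""
    report = CurationReport()
    seen = {}
    kept = []
    for r in dataset.records:
        key = (*_group_key(dataset, r), r.value)
        if key in seen:
            report.log(r.record_id, "merged_dupI", f"duplicate of {seen[key]}")
        else:
            seen[key] = r.record_id
            kept.append(r)
    comps = {r.compound_id: dataset.compounds[r.compound_id] for r in kept}
    return Dataset(comps, kept, dataset.schema), report


def duplicate_analysis_II(dataset: Dataset, threshold_spec=None, diff_cutoff: float = 0.5):
    """Resolve groups identical in (structure, conditions) with differing values.

    ``threshold_spec`` maps an endpoint value to its class (defaults to the
    standard cut-off labeler); ``diff_cutoff`` is the value range (max−min,
    native units) below which values are averaged.
    """
    labeler = threshold_spec or label_endpoint
    report = CurationReport()
    groups: dict = {}
    order: list = []
    for r in dataset.records:
        key = _group_key(dataset, r)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    kept = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            kept.append(members[0])
            continue
        values = [m.value for m in members]
        numeric = all(isinstance(v, (int, float)) for v in values)
        if numeric:
            vmax, vmin = max(values), min(values)
            if vmax - vmin < diff_cutoff:
                mean = float(np.mean(values))
                first = members[0]
                first.value = mean
                if first.class_label is not None:
                    first.class_label = labeler(first.endpoint_name, mean)
                kept.append(first)
                for m in members[1:]:
                    report.log(
                        m.record_id,
                        "averaged_dupII",
                        f"collapsed into {first.record_id} (mean {mean:g})",
                    )
                continue
            classes = {labeler(m.endpoint_name, m.value) for m in members}
        else:
            classes = {labeler(m.endpoint_name, m.value) for m in members}
        if len(classes) == 1:
            median = float(np.median(values)) if numeric else None
            if numeric:
                best = min(members, key=lambda m: abs(m.value - median))
            else:
                best = members[0]
            kept.append(best)
            for m in members:
                if m is not best:
                    report.log(
                        m.record_id,
                        "kept_same_class_dupII",
                        f"same-class duplicate of kept {best.record_id}",
                    )
        else:
            for m in members:
                report.log(m.record_id, "removed_conflicting", "class-conflicting duplicate group")

    comps = {r.compound_id: dataset.compounds[r.compound_id] for r in kept}
    return Dataset(comps, kept, dataset.schema), report


def curate(dataset: Dataset, threshold_spec=None, diff_cutoff: float = 0.5):
    """Full curation chain: chemistry → missing endpoints → dup I → dup II.

    Returns ``(curated_dataset, report)``.  Running the chain on its own
    output is a fixed point.  Endpoint values are never altered except by
    the stated duplicate averaging.
    """
    report = CurationReport()
    curated_compounds, chem_report = curate_chemistry(dataset.compounds.values())
    report.merge(chem_report)
    removal_reason = {
        ident: action
        for ident, action, _ in chem_report.audit
        if action.startswith("removed_")
    }
    surviving = {c.id: c for c in curated_compounds}
    records = []
    for r in dataset.records:
        if r.compound_id in surviving:
            records.append(r)
        else:
            report.log(
                r.record_id,
                removal_reason.get(r.compound_id, "removed_unparseable"),
                "compound removed in chemical curation",
            )
    ds = Dataset(
        {cid: surviving[cid] for cid in {r.compound_id for r in records}},
        records,
        dataset.schema,
    )
    ds, rep = drop_missing_endpoints(ds)
    report.merge(rep)
    ds, rep = duplicate_analysis_I(ds)
    report.merge(rep)
    ds, rep = duplicate_analysis_II(ds, threshold_spec=threshold_spec, diff_cutoff=diff_cutoff)
    report.merge(rep)
    logger.info(
        "curation: %d -> %d records (%d removed, %d collapsed)",
        len(dataset.records),
        len(ds.records),
        report.removed(),
        report.collapsed(),
    )
    return ds, report
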