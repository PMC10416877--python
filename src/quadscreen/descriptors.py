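"""Molecular descriptors behind a pluggable backend, plus pretreatment.

The builtin backend is a self-contained set of 2-D physicochemical and
topological descriptors (atom/bond/ring counts, molecular weight, an
atom-contribution logP estimate, H-bond donor/acceptor counts, Balaban,
Bertz, chi and kappa indices, TPSA, ...) together with the 166-key MACCS
structural fingerprint — enough to drive the whole pipeline with no
external descriptor tool.  A precomputed backend adapts third-party (or
synthetic) descriptor tables into the same matrix shape.  Models record
which backend produced their matrix and refuse matrices from any other.

Pretreatment removes near-constant columns (variance cut-off, default
1e-4) and then greedily filters highly inter-correlated columns (|Pearson
r| cut-off, default 0.99, first-kept-wins in input column order).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdMolDescriptors

__all__ = [
    "BUILTIN_BACKEND",
    "PrecomputedBackend",
    "compute_descriptors",
    "maccs_fingerprints",
    "pretreat",
    "PretreatReport",
    "drop_missing_descriptor_rows",
]

BUILTIN_BACKEND = "builtin-2d-v1"

# name -> callable(mol); the documented builtin set.
_BUILTIN_FUNCS = [
    ("MolWt", Descriptors.MolWt),
    ("HeavyAtomCount", lambda m: m.GetNumHeavyAtoms()),
    ("NumHeteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
    ("NumHDonors", rdMolDescriptors.CalcNumHBD),
    ("NumHAcceptors", rdMolDescriptors.CalcNumHBA),
    ("NumRotatableBonds", rdMolDescriptors.CalcNumRotatableBonds),
    ("RingCount", rdMolDescriptors.CalcNumRings),
    ("AromaticRingCount", rdMolDescriptors.CalcNumAromaticRings),
    ("AliphaticRingCount", rdMolDescriptors.CalcNumAliphaticRings),
    ("SaturatedRingCount", rdMolDescriptors.CalcNumSaturatedRings),
    ("AromaticHeterocycleCount", rdMolDescriptors.CalcNumAromaticHeterocycles),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("LabuteASA", rdMolDescriptors.CalcLabuteASA),
    ("MolLogP", Crippen.MolLogP),
    ("MolMR", Crippen.MolMR),
    ("BalabanJ", Descriptors.BalabanJ),
    ("BertzCT", Descriptors.BertzCT),
    ("HallKierAlpha", rdMolDescriptors.CalcHallKierAlpha),
    ("Chi0", Descriptors.Chi0),
    ("Chi1", Descriptors.Chi1),
    ("Chi0v", Descriptors.Chi0v),
    ("Chi1v", Descriptors.Chi1v),
    ("Kappa1", Descriptors.Kappa1),
    ("Kappa2", Descriptors.Kappa2),
    ("Kappa3", Descriptors.Kappa3),
]

_N_MACCS = 166


@dataclass(frozen=True)
class PrecomputedBackend:
    """External-backend adapter: a descriptor table keyed by compound id.

    Used both for third-party descriptor tools (whose output is mapped
    into the common matrix shape) and for synthetic benchmark data whose
    descriptor columns carry planted signal.
    """

    table: pd.DataFrame
    name: str = "precomputed"


def _builtin_row(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    values = {}
    for name, func in _BUILTIN_FUNCS:
        values[name] = float(func(mol))
    bits = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 is unused
    for i in range(1, _N_MACCS + 1):
        values[f"MACCS_{i}"] = float(bits.GetBit(i))
    return values


def compute_descriptors(compounds, backend="builtin") -> pd.DataFrame:
    """Descriptor matrix for curated compounds: rows = compound ids.

    ``backend`` is ``"builtin"`` or a :class:`PrecomputedBackend`.  A
    per-compound computation failure produces a row of NaN (missing-value
    mask), never an abort.  The producing backend is recorded in
    ``frame.attrs["backend"]``.
    """
    ids = [c.id for c in compounds]
    if isinstance(backend, PrecomputedBackend):
        frame = backend.table.reindex(ids).astype(float)
        frame.attrs["backend"] = backend.name
        return frame
    if backend != "builtin":
        raise ValueError(f"unknown backend {backend!r}")
    rows, index = [], []
    columns = None
    for c in compounds:
        row = _builtin_row(c.smiles)
        if row is not None and columns is None:
            columns = list(row)
        rows.append(row)
        index.append(c.id)
    if columns is None:
        columns = [name for name, _ in _BUILTIN_FUNCS] + [
            f"MACCS_{i}" for i in range(1, _N_MACCS + 1)
        ]
    data = [
        [np.nan] * len(columns) if r is None else [r[c] for c in columns] for r in rows
    ]
    frame = pd.DataFrame(data, index=index, columns=columns, dtype=float)
    frame.attrs["backend"] = BUILTIN_BACKEND
    return frame


def maccs_fingerprints(compounds) -> pd.DataFrame:
    """166-key MACCS fingerprints (0/1), rows = compound ids.

    Computed from structure, independently of the descriptor backend;
    used by the similarity branch of the applicability domain.
    """
    rows, index = [], []
    for c in compounds:
        mol = Chem.MolFromSmiles(c.smiles)
        if mol is None:
            rows.append(np.full(_N_MACCS, np.nan))
        else:
            bits = MACCSkeys.GenMACCSKeys(mol)
            rows.append(np.array([bits.GetBit(i) for i in range(1, _N_MACCS + 1)], dtype=float))
        index.append(c.id)
    return pd.DataFrame(rows, index=index, columns=[f"MACCS_{i}" for i in range(1, _N_MACCS + 1)])


@dataclass
class PretreatReport:
    removed_low_variance: list = dc_field(default_factory=list)
    removed_correlated: list = dc_field(default_factory=list)  # (dropped, kept_partner, r)


def pretreat(
    matrix: pd.DataFrame,
    variance_cutoff: float = 1e-4,
    correlation_cutoff: float = 0.99,
):
    """Variance and correlation filtering of a descriptor matrix.

    Columns with sample variance below ``variance_cutoff`` are removed;
    the remaining columns are scanned in input order and a column is
    dropped when its |Pearson r| with an already-retained column reaches
    ``correlation_cutoff`` (greedy, first-kept-wins, deterministic).
    """
    if matrix is None or matrix.shape[1] == 0 or matrix.shape[0] == 0:
        raise ValueError("empty descriptor matrix")
    report = PretreatReport()
    variances = matrix.var(axis=0, ddof=1, skipna=True)
    low = variances.isna() | (variances < variance_cutoff)
    report.removed_low_variance = list(matrix.columns[low])
    kept = matrix.loc[:, ~low.values]

    corr = kept.corr().abs().to_numpy() if kept.shape[1] > 1 else np.ones((kept.shape[1],) * 2)
    retained: list[int] = []
    for j in range(kept.shape[1]):
        clash = None
        for i in retained:
            r = corr[i, j]
            if np.isfinite(r) and r >= correlation_cutoff:
                clash = (i, r)
                break
        if clash is None:
            retained.append(j)
        else:
            report.removed_correlated.append(
                (kept.columns[j], kept.columns[clash[0]], float(clash[1]))
            )
    out = kept.iloc[:, retained]
    out.attrs = dict(matrix.attrs)
    return out, report


def drop_missing_descriptor_rows(matrix: pd.DataFrame, dataset):
    """Remove compounds with any missing value in the retained columns.

    Drops the corresponding rows from the matrix and their endpoint
    records from the dataset.  Returns (matrix, dataset, dropped_ids).
    """
    from .chemtable import Dataset

    bad = matrix.index[matrix.isna().any(axis=1)]
    dropped = list(bad)
    if not dropped:
        return matrix, dataset, dropped
    keep_matrix = matrix.drop(index=bad)
    keep_matrix.attrs = dict(matrix.attrs)
    records = [r for r in dataset.records if r.compound_id not in set(dropped)]
    comps = {r.compound_id: dataset.compounds[r.compound_id] for r in records}
    return keep_matrix, Dataset(comps, records, dataset.schema), dropped
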