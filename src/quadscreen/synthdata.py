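"""Synthetic multi-condition QSAR datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes —
compounds measured under heterogeneous experimental conditions, with a
condition-dependent relationship between descriptors and activity — so
every stage (curation, pretreatment, the Box–Jenkins transform, GA
selection, LDA/RF fitting, validation, AD) is testable offline.

Mechanism.  Structures are drawn from a combinatorial fragment library
(scaffold templates × substituents), guaranteeing parseable molecules
that survive curation.  Each record gets a condition profile; the
informative descriptor columns are Gaussians shifted additively by the
record's condition category, and the class is a linear rule on the
*condition-centered* informative descriptors — so the raw columns are
confounded by condition and the Box–Jenkins deviation-from-condition-mean
transform is exactly what recovers the signal.  Labels are flipped with a
small probability (label noise), and the continuous endpoint is
back-computed from the final class so that threshold labeling reproduces
it exactly.  Exact and near-duplicate rows and salt/mixture variants are
injected at configurable rates to exercise both duplicate-analysis stages
and salt stripping.

The structures carry no activity signal: synthetic descriptors enter the
pipeline through the precomputed-backend adapter, exactly like an
external descriptor tool's output would.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from rdkit import Chem

from .applicability import build_ad_reference
from .chemtable import ConditionSchema, dataset_from_frame
from .curation import curate, standardize_structure
from .descriptors import (
    PrecomputedBackend,
    compute_descriptors,
    drop_missing_descriptor_rows,
    maccs_fingerprints,
    pretreat,
)
from .modeling import (
    GAParams,
    evaluate,
    fit_lda,
    fit_rf,
    ga_select,
    split_external,
    split_train_test,
)
from .multitask import fit_condition_means, transform

__all__ = ["SynthSpec", "SynthResult", "generate", "recovery_benchmark"]

SYNTH_BACKEND = "synthetic-gaussian-v1"

# scaffold templates ({a}/{b} are substituent slots) and substituents;
# invalid combinations are skipped at generation time, so the library is
# always a set of valid, unique, curation-stable structures.
_TEMPLATES = (
    "{a}c1ccc({b})cc1",
    "{a}c1cccc({b})c1",
    "{a}c1ccc({b})nc1",
    "{a}C1CCC({b})CC1",
    "{a}c1ccc2cc({b})ccc2c1",
    "{a}c1ccc(-c2ccc({b})cc2)cc1",
    "{a}c1ccc({b})o1",
    "{a}c1ccc({b})s1",
    "{a}c1nc({b})cs1",
    "{a}c1cc({b})cc(C)c1",
)
_SUBSTITUENTS = (
    "C", "CC", "CCC", "CC(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)OC", "C(=O)N",
    "C=C", "S", "SC", "CO",
)
_SALTS = (".Cl", ".Br", ".[Na+].[Cl-]", ".O", ".OS(=O)(=O)O")


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters; the seed fully determines the output."""

    n_compounds: int = 600
    condition_fields: tuple = (
        ("buffer", ("K100", "Na100", "KLi90")),
        ("assay", ("FRET", "UV")),
    )
    #: additive descriptor shift per (field, category); the planted
    #: condition-dependence the Box–Jenkins transform must absorb.
    offsets: tuple = (
        ("buffer", (("K100", 1.5), ("Na100", 0.0), ("KLi90", -1.5))),
        ("assay", (("FRET", 0.0), ("UV", 0.0))),
    )
    n_informative: int = 2
    n_noise: int = 20
    endpoint: str = "dTm"
    label_noise: float = 0.1
    duplicate_rate: float = 0.05
    salt_rate: float = 0.05
    #: minimum |discriminant score| of the class rule: descriptor draws
    #: closer to the boundary are redrawn, so the rule is learnable and
    #: essentially all irreducible error comes from the label noise.
    boundary_margin: float = 0.5
    #: class margin of the back-computed endpoint, in endpoint units;
    #: larger than the duplicate-averaging window so injected
    #: near-duplicates can never flip class.
    margin: float = 0.6
    seed: int = 42

    def __post_init__(self):
        for rate in (self.label_noise, self.duplicate_rate, self.salt_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")


@dataclass
class SynthResult:
    table: pd.DataFrame  # raw delimited-style table (with injected artifacts)
    descriptors: pd.DataFrame  # synthetic descriptor matrix, rows = compound ids
    schema: ConditionSchema
    truth: dict


def _fragment_library(n: int, rng: np.random.Generator) -> list:
    """n unique structures whose curated canonical forms are distinct."""
    seen = set()
    out = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 200 * n:
            raise RuntimeError("fragment library exhausted; lower n_compounds")
        template = _TEMPLATES[rng.integers(0, len(_TEMPLATES))]
        a = _SUBSTITUENTS[rng.integers(0, len(_SUBSTITUENTS))]
        b = _SUBSTITUENTS[rng.integers(0, len(_SUBSTITUENTS))]
        smi = template.format(a=a, b=b)
        if Chem.MolFromSmiles(smi) is None:
            continue
        canonical, _ = standardize_structure(smi)
        if canonical is None or canonical in seen:
            continue
        seen.add(canonical)
        out.append(smi)
    return out


def generate(spec: SynthSpec | None = None):
    """Generate a raw multi-condition table plus its ground truth.

    Returns a :class:`SynthResult`; ``truth`` records the true (pre-noise)
    classes, the planted informative columns and weights, the condition
    offsets, and the ids of injected duplicate/salt artifacts.
    """
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    fields = tuple(f for f, _ in spec.condition_fields)
    categories = {f: tuple(cats) for f, cats in spec.condition_fields}
    offsets = {f: dict(pairs) for f, pairs in spec.offsets}
    schema = ConditionSchema("synthetic", fields, spec.endpoint)

    smiles = _fragment_library(spec.n_compounds, rng)
    ids = [f"S{i:05d}" for i in range(spec.n_compounds)]

    info_cols = [f"D{i + 1:02d}" for i in range(spec.n_informative)]
    noise_cols = [f"N{i + 1:02d}" for i in range(spec.n_noise)]
    weights = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)

    rows = []
    desc_rows = {}
    true_class = {}
    for cid, smi in zip(ids, smiles):
        cats = {f: categories[f][rng.integers(0, len(categories[f]))] for f in fields}
        shift = sum(offsets[f].get(cats[f], 0.0) for f in fields)
        e = rng.normal(size=spec.n_informative)
        while abs(float(weights @ e)) < spec.boundary_margin:
            e = rng.normal(size=spec.n_informative)
        # the shift enters along the weight direction, so the raw columns
        # are confounded by condition and only the condition-centered
        # (Box-Jenkins) columns carry the clean class signal
        x_info = weights * shift + e
        x_noise = rng.normal(size=spec.n_noise)
        desc_rows[cid] = np.concatenate([x_info, x_noise])

        margin_score = float(weights @ e)
        y_true = int(margin_score > 0)
        y = 1 - y_true if rng.random() < spec.label_noise else y_true
        true_class[cid] = y_true

        spread = spec.margin + 2.0 * abs(margin_score)
        value = 15.0 + spread if y == 1 else 15.0 - spread
        value = float(np.round(max(value, 0.1), 3))
        rows.append({"compound_id": cid, "smiles": smi, **cats, spec.endpoint: value})

    table = pd.DataFrame(rows)

    # inject duplicates: half exact copies, half value-jittered (< 0.25,
    # same class; range below the 0.5 averaging window)
    n_dup = int(np.floor(spec.n_compounds * spec.duplicate_rate))
    dup_sources = rng.choice(spec.n_compounds, size=n_dup, replace=False) if n_dup else []
    injected_duplicates = []
    extra = []
    for j, src in enumerate(dup_sources):
        row = dict(table.iloc[src])
        if j % 2 == 1:
            jitter = float(rng.uniform(0.05, 0.24)) * (1 if rng.random() < 0.5 else -1)
            row[spec.endpoint] = float(np.round(row[spec.endpoint] + jitter, 3))
        extra.append(row)
        injected_duplicates.append(row["compound_id"])
    if extra:
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)

    # inject salt/solvate variants of existing rows' structures in place
    n_salt = int(np.floor(spec.n_compounds * spec.salt_rate))
    salt_rows = rng.choice(spec.n_compounds, size=n_salt, replace=False) if n_salt else []
    injected_salts = []
    for src in salt_rows:
        salt = _SALTS[rng.integers(0, len(_SALTS))]
        table.loc[src, "smiles"] = table.loc[src, "smiles"] + salt
        injected_salts.append(table.loc[src, "compound_id"])

    descriptors = pd.DataFrame(
        np.vstack([desc_rows[cid] for cid in ids]),
        index=ids,
        columns=info_cols + noise_cols,
    )
    truth = {
        "informative_columns": info_cols,
        "weights": weights.tolist(),
        "offsets": {f: dict(pairs) for f, pairs in spec.offsets},
        "true_class": true_class,
        "injected_duplicates": injected_duplicates,
        "injected_salts": injected_salts,
    }
    return SynthResult(table=table, descriptors=descriptors, schema=schema, truth=truth)


def recovery_benchmark(
    spec: SynthSpec | None = None,
    n_features: int = 2,
    ga_params: GAParams | None = None,
    split_method: str = "random",
    use_modified: bool = True,
    cv_folds: int | None = None,
):
    """Run the full pipeline on generated data and score it against truth.

    curate → (precomputed synthetic) descriptors → pretreat → stratified
    external split → condition means on the modeling set → Box–Jenkins
    transform → train/test split → GA(Wilks λ) → LDA and RF → metric
    suite on train/test/external/external-in-AD.

    ``use_modified=False`` skips the Box–Jenkins transform and models the
    raw (pretreated) descriptors instead — the control arm showing what
    the condition-modified descriptors buy.

    Returns a report dict with per-model validation reports, the selected
    columns and the recall of the planted informative descriptors.
    """
    spec = spec or SynthSpec()
    base_seed = int(spec.seed) % (2**31 - 10)
    res = generate(spec)
    ds, rejects = dataset_from_frame(res.table, res.schema, id_col="compound_id")
    n_raw = len(ds.records)
    ds, report = curate(ds)
    ds = ds.labeled()

    backend = PrecomputedBackend(res.descriptors, name=SYNTH_BACKEND)
    desc = compute_descriptors(list(ds.compounds.values()), backend)
    desc, pre_report = pretreat(desc)
    desc, ds, dropped = drop_missing_descriptor_rows(desc, ds)

    plan = split_external(ds.records, fraction=0.2, seed=base_seed + 1)
    modeling = ds.subset(plan.first)
    external = ds.subset(plan.second)

    labels = {r.record_id: r.class_label for r in ds.records}
    if use_modified:
        means = fit_condition_means(modeling.records, desc)
        X_modeling = transform(modeling.records, desc, means)
        X_external = transform(external.records, desc, means)
    else:
        means = fit_condition_means(modeling.records, desc)  # still bundled
        rec_rows = lambda records: pd.DataFrame(
            [desc.loc[r.compound_id] for r in records],
            index=[r.record_id for r in records],
        )
        X_modeling, X_external = rec_rows(modeling.records), rec_rows(external.records)

    tt = split_train_test(
        [r.record_id for r in modeling.records],
        method=split_method,
        fraction=0.2,
        seed=base_seed + 2,
        matrix=X_modeling,
    )
    X_train, X_test = X_modeling.loc[list(tt.first)], X_modeling.loc[list(tt.second)]
    y_train = np.array([labels[r] for r in tt.first])
    y_test = np.array([labels[r] for r in tt.second])
    y_ext = np.array([labels[r.record_id] for r in external.records])

    ga = ga_select(
        X_train,
        y_train,
        n_features=n_features,
        ga_params=ga_params or GAParams(seed=base_seed + 3),
        fitness="wilks",
    )
    cols = list(ga.columns)
    selected_descriptors = sorted({c.split("|")[0] for c in cols})
    planted = set(res.truth["informative_columns"])
    recall = len(planted & set(selected_descriptors)) / len(planted)

    # AD reference from the training records
    compound_of = {r.record_id: r.compound_id for r in ds.records}
    train_comp_ids = [compound_of[r] for r in tt.first]
    fps_all = maccs_fingerprints(list(ds.compounds.values()))
    fps_train = fps_all.loc[train_comp_ids]
    ad_ref = build_ad_reference(fps_train, X_train[cols])

    out: dict = {
        "n_raw_records": n_raw,
        "n_curated_records": len(ds.records),
        "selected_columns": cols,
        "selected_descriptors": selected_descriptors,
        "ga_recall": recall,
        "ga_fitness": ga.fitness,
        "split": {"train": len(tt.first), "test": len(tt.second), "external": len(external.records)},
        # the GA's search problem, exposed for oracle cross-checks
        "_train_matrix": X_train,
        "_train_labels": y_train,
    }
    for kind, fit in (("lda", fit_lda), ("rf", lambda X, y: fit_rf(X, y, seed=base_seed + 4))):
        model = fit(X_train[cols], y_train)
        model.backend = SYNTH_BACKEND
        model.condition_means = means
        model.ad_reference = ad_ref
        ext_fps = fps_all.loc[[compound_of[r.record_id] for r in external.records]]
        from .applicability import ad_verdict

        in_ad = np.array(
            [
                ad_verdict(ext_fps.iloc[i].to_numpy(), X_external[cols].iloc[i].to_numpy(), ad_ref).inside
                for i in range(len(external.records))
            ]
        )
        reports = {
            "train": evaluate(model, X_train[cols], y_train, folds=cv_folds),
            "test": evaluate(model, X_test[cols], y_test),
            "external": evaluate(model, X_external[cols], y_ext),
        }
        if in_ad.any():
            reports["external_in_ad"] = evaluate(
                model, X_external[cols].iloc[in_ad], y_ext[in_ad]
            )
        out[kind] = {"model": model, "reports": reports, "external_in_ad_fraction": float(in_ad.mean())}
    return out
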