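import numpy as np
import pandas as pd
import pytest

from quadscreen.applicability import build_ad_reference
from quadscreen.chemtable import CompoundRecord
from quadscreen.descriptors import PrecomputedBackend, compute_descriptors, maccs_fingerprints
from quadscreen.modeling import fit_lda
from quadscreen.multitask import fit_condition_means, transform
from quadscreen.screening import (
    ConditionGrid,
    consensus_positive,
    enumerate_conditions,
    lipinski_filter,
    load_condition_config,
    screen,
)

from conftest import make_dataset


# --- condition grids ---

@pytest.mark.parametrize(
    "model,size",
    [("selectivity", 18), ("interaction", 24), ("stabilization", 24), ("cytotoxicity", 10)],
)
def test_default_grid_sizes(model, size):
    grid = ConditionGrid.from_config(model)
    assert grid.size == size
    assert len(grid.enumerate()) == size


def test_enumeration_deterministic_schema_order():
    a = enumerate_conditions("stabilization")
    b = enumerate_conditions("stabilization")
    assert a == b
    first = a[0]
    assert first.fields[:4] == ("sequence", "buffer", "assay", "lgr")
    assert first["lgr"] == 5  # config order


def test_oncogene_derived_from_sequence():
    profiles = enumerate_conditions("interaction")
    targets = load_condition_config()["targets"]
    for p in profiles:
        assert p["oncogene"] == targets[p["sequence"]]


def test_unknown_model_grid_errors():
    with pytest.raises(KeyError):
        ConditionGrid.from_config("docking")


def test_grid_size_formula_for_custom_grids():
    cfg = {
        "targets": {},
        "models": {
            "toy": {
                "endpoint": "dTm",
                "fields": ["a", "b", "c"],
                "grid": {"a": [1, 2, 3], "b": ["x", "y"], "c": [0]},
            }
        },
    }
    grid = ConditionGrid.from_config("toy", cfg)
    assert grid.size == 6 and len(grid.enumerate()) == 6


def test_grid_field_outside_schema_errors():
    cfg = {
        "targets": {},
        "models": {"toy": {"endpoint": "dTm", "fields": ["a"], "grid": {"a": [1], "b": [2]}}},
    }
    with pytest.raises(ValueError, match="not in model schema"):
        ConditionGrid.from_config("toy", cfg)


# --- Lipinski ---

def test_lipinski_ethanol_passes():
    passed, failed = lipinski_filter([CompoundRecord("e", "CCO")])
    assert len(passed) == 1 and not failed


def test_lipinski_c40_alkane_fails_mw_and_logp():
    c40 = CompoundRecord("c40", "C" * 40)
    passed, failed = lipinski_filter([c40])
    assert not passed
    assert set(failed[0][1]) == {"MW>500", "logP>5"}


def test_lipinski_empty_input():
    assert lipinski_filter([]) == ([], [])


def test_lipinski_one_violation_allowed_when_configured():
    # cholesterol: logP > 5 is its only violation
    chol = CompoundRecord("chol", "CC(C)CCCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C")
    strict, _ = lipinski_filter([chol])
    lenient, _ = lipinski_filter([chol], max_violations=1)
    assert not strict and len(lenient) == 1


# --- screening engine on a tiny synthetic model ---

def _toy_world():
    """Two compounds, one 2-condition-field model on synthetic descriptors."""
    ds = make_dataset(
        [
            ("CCO", {"buffer": "K", "assay": "F"}, 20.0),
            ("CCN", {"buffer": "Na", "assay": "F"}, 3.0),
            ("CCC", {"buffer": "K", "assay": "U"}, 25.0),
            ("CCCl", {"buffer": "Na", "assay": "U"}, 1.0),
        ]
    ).labeled()
    table = pd.DataFrame(
        {"D1": [2.0, -2.0, 2.5, -1.5]}, index=["C000", "C001", "C002", "C003"]
    )
    desc = compute_descriptors(list(ds.compounds.values()), PrecomputedBackend(table, "synth-test"))
    means = fit_condition_means(ds.records, desc)
    X = transform(ds.records, desc, means)
    y = [r.class_label for r in ds.records]
    model = fit_lda(X, y)
    model.backend = "synth-test"
    model.condition_means = means
    fps = maccs_fingerprints(list(ds.compounds.values()))
    model.ad_reference = build_ad_reference(fps, X)
    grid = ConditionGrid(
        model="stab", fields=("buffer", "assay"),
        axes={"buffer": ["K", "Na"], "assay": ["F", "U"]},
    )
    return ds, desc, model, grid


def test_screen_row_counts_follow_grid_size():
    ds, desc, model, grid = _toy_world()
    compounds = list(ds.compounds.values())[:2]
    matrix = screen(compounds, {"stab": model}, grids={"stab": grid},
                    descriptor_matrix=desc)
    assert len(matrix) == 2 * 4  # compounds x grid size
    assert set(matrix["compound_id"]) == {c.id for c in compounds}
    assert matrix["prediction"].isin([0, 1]).all()
    assert {"in_ad", "buffer", "assay"} <= set(matrix.columns)


def test_screen_backend_mismatch_refused():
    ds, desc, model, grid = _toy_world()
    model.backend = "some-other-backend"
    with pytest.raises(ValueError, match="backend mismatch"):
        screen(list(ds.compounds.values()), {"stab": model}, grids={"stab": grid},
               descriptor_matrix=desc)


def test_screen_order_independent():
    ds, desc, model, grid = _toy_world()
    compounds = list(ds.compounds.values())
    m1 = screen(compounds, {"stab": model}, grids={"stab": grid}, descriptor_matrix=desc)
    m2 = screen(compounds[::-1], {"stab": model}, grids={"stab": grid}, descriptor_matrix=desc)
    key = ["compound_id", "buffer", "assay"]
    s1 = m1.sort_values(key).reset_index(drop=True)
    s2 = m2.sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(s1, s2)


def test_screen_reports_predictions_outside_ad():
    ds, desc, model, grid = _toy_world()
    # force every method to reject: impossible similarity, negative
    # distance budget, negative leverage limit
    model.ad_reference.thresholds.update({"tanimoto_min": 1.01, "leverage_hstar": -1.0})
    model.ad_reference.nn_mean = -1.0
    model.ad_reference.nn_sd = 0.0
    matrix = screen(list(ds.compounds.values()), {"stab": model},
                    grids={"stab": grid}, descriptor_matrix=desc)
    assert (~matrix["in_ad"].astype(bool)).all()
    assert matrix["prediction"].notna().all()  # still reported


# --- consensus ---

def _random_matrix(rng, n_compounds=12):
    rows = []
    for i in range(n_compounds):
        for m in ("selectivity", "interaction", "stabilization", "cytotoxicity"):
            for c in range(int(rng.integers(1, 4))):
                rows.append(
                    {"model": m, "compound_id": f"c{i}", "prediction": int(rng.integers(0, 2))}
                )
    return pd.DataFrame(rows)


def test_consensus_all_conditions_subset_of_any_condition():
    rng = np.random.default_rng(17)
    for _ in range(25):
        m = _random_matrix(rng)
        any_c = set(consensus_positive(m, rule="any_condition"))
        all_c = set(consensus_positive(m, rule="all_conditions"))
        assert all_c <= any_c


def test_consensus_requires_all_four_models():
    rng = np.random.default_rng(3)
    m = _random_matrix(rng)
    m = m[m["model"] != "cytotoxicity"]
    with pytest.raises(ValueError, match="missing model"):
        consensus_positive(m)


def test_consensus_negative_everywhere_in_one_model_excluded():
    rows = []
    for m in ("selectivity", "interaction", "stabilization", "cytotoxicity"):
        pred = 0 if m == "interaction" else 1
        rows.append({"model": m, "compound_id": "c0", "prediction": pred})
    frame = pd.DataFrame(rows)
    assert consensus_positive(frame, rule="any_condition") == []
    assert consensus_positive(frame, rule="all_conditions") == []


def test_consensus_positive_everywhere_retained_under_both_rules():
    rows = [
        {"model": m, "compound_id": "c0", "prediction": 1}
        for m in ("selectivity", "interaction", "stabilization", "cytotoxicity")
    ]
    frame = pd.DataFrame(rows)
    assert consensus_positive(frame, rule="any_condition") == ["c0"]
    assert consensus_positive(frame, rule="all_conditions") == ["c0"]
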