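import pytest

from quadscreen.chemtable import (
    CompoundRecord,
    ConditionProfile,
    ConditionSchema,
    Dataset,
    EndpointRecord,
)
from quadscreen.synthdata import SynthSpec, generate, recovery_benchmark

STAB_SCHEMA = ConditionSchema("stab", ("buffer", "assay"), "dTm")


def make_dataset(rows, schema=STAB_SCHEMA):
    """Build a Dataset from (smiles, conditions-dict, value) triples.

    Distinct SMILES strings become distinct compounds; repeated SMILES
    share one compound record.
    """
    compounds, records = {}, []
    smi_to_id = {}
    for i, (smi, conds, value) in enumerate(rows):
        if smi not in smi_to_id:
            cid = f"C{len(smi_to_id):03d}"
            smi_to_id[smi] = cid
            compounds[cid] = CompoundRecord(id=cid, smiles=smi)
        records.append(
            EndpointRecord(
                record_id=f"R{i:03d}",
                compound_id=smi_to_id[smi],
                condition=ConditionProfile.from_mapping(schema, conds),
                endpoint_name=schema.endpoint,
                value=value,
            )
        )
    return Dataset(compounds, records, schema)


@pytest.fixture(scope="session")
def default_generated():
    """The default synthetic dataset (n=600, seed 42)."""
    return generate(SynthSpec())


@pytest.fixture(scope="session")
def default_benchmark():
    """Full-pipeline recovery benchmark on the default synthetic dataset."""
    return recovery_benchmark()


@pytest.fixture(scope="session")
def small_generated():
    """A small synthetic dataset for fast structural tests."""
    return generate(SynthSpec(n_compounds=120, seed=7))
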