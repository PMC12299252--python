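import random

import pytest

from screenclean.records import ActivityRecord, CuratedDataset


def make_record(
    mol: str = "M1",
    smiles: str = "c1ccccc1",
    value: float | None = 100.0,
    units: str | None = "nM",
    relation: str | None = "=",
    assay: str = "A",
    std: str | None = None,
    pic50: float | None = None,
    **kwargs,
) -> ActivityRecord:
    return ActivityRecord(
        molecule_id=mol,
        smiles_raw=smiles,
        value=value,
        units=units,
        relation=relation,
        assay_id=assay,
        smiles_std=std,
        pic50=pic50,
        **kwargs,
    )


def cleaned_dataset(records, stage="standard_cleaned") -> CuratedDataset:
    """Dataset at a post-cleaning stage built directly from records."""
    return CuratedDataset(records=list(records), stage=stage)


@pytest.fixture
def molecule_x_dataset() -> CuratedDataset:
    """Molecule X in assay A (global count 5, values 7.2/7.8) and assay B
    (count 2, value 8.9), padded with filler molecules so the global
    assay counts are exactly 5 and 2."""
    recs = [
        make_record("X", std="SMI_X", assay="A", pic50=7.2),
        make_record("X", std="SMI_X", assay="A", pic50=7.8),
        make_record("X", std="SMI_X", assay="B", pic50=8.9),
        make_record("F1", std="SMI_F1", assay="A", pic50=5.0),
        make_record("F2", std="SMI_F2", assay="A", pic50=5.1),
        make_record("F3", std="SMI_F3", assay="A", pic50=5.2),
        make_record("F4", std="SMI_F4", assay="B", pic50=5.3),
    ]
    return cleaned_dataset(recs)


def random_table(rng: random.Random, max_records=50, max_assays=8, max_molecules=10) -> CuratedDataset:
    """Random standard-cleaned table for oracle-equivalence checks."""
    n = rng.randint(1, max_records)
    n_assays = rng.randint(1, max_assays)
    n_mols = rng.randint(1, max_molecules)
    recs = []
    for i in range(n):
        mol = rng.randint(1, n_mols)
        recs.append(
            make_record(
                mol=f"M{mol}",
                std=f"SMI_{mol}",
                assay=f"A{rng.randint(1, n_assays)}",
                pic50=round(rng.uniform(4.0, 10.0), rng.choice([1, 2, 6])),
            )
        )
    return cleaned_dataset(recs)
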