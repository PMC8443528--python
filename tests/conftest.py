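import pytest

from tmshift import (
    MutationDataset,
    MutationEntry,
    PropertyTable,
    SyntheticConfig,
    simulate_dataset,
)


def make_entry(**kw) -> MutationEntry:
    base = dict(
        protein_id="P001",
        chain="A",
        residue_number=10,
        wt_aa="V",
        mut_aa="A",
        tm_wt=60.0,
        d_tm=-3.0,
        ph=7.0,
        technique="CD",
        rsa=0.2,
        avg_b=25.0,
        ss_code=1,
    )
    base.update(kw)
    return MutationEntry(**base)


@pytest.fixture(scope="session")
def table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture()
def small_dataset() -> MutationDataset:
    """Ten hand-built annotated entries over two proteins."""
    entries = [
        make_entry(protein_id="P001", residue_number=1, wt_aa="V", mut_aa="A", d_tm=-1.0, ph=7.0),
        make_entry(protein_id="P001", residue_number=2, wt_aa="V", mut_aa="A", d_tm=-3.0, ph=7.0),
        make_entry(protein_id="P001", residue_number=3, wt_aa="V", mut_aa="A", d_tm=-5.0, ph=7.0),
        make_entry(protein_id="P001", residue_number=4, wt_aa="V", mut_aa="A", d_tm=-7.0, ph=7.0),
        make_entry(protein_id="P001", residue_number=5, wt_aa="I", mut_aa="G", d_tm=-9.5, ph=7.0),
        make_entry(protein_id="P002", residue_number=6, wt_aa="D", mut_aa="K", d_tm=4.5, ph=3.0),
        make_entry(protein_id="P002", residue_number=7, wt_aa="E", mut_aa="L", d_tm=2.0, ph=3.0),
        make_entry(protein_id="P002", residue_number=8, wt_aa="G", mut_aa="W", d_tm=0.0, ph=5.0),
        make_entry(protein_id="P002", residue_number=9, wt_aa="K", mut_aa="N", d_tm=1.5, ph=9.0),
        make_entry(protein_id="P002", residue_number=10, wt_aa="T", mut_aa="V", d_tm=-2.5, ph=9.0),
    ]
    return MutationDataset(entries=entries, provenance="hand fixture")


@pytest.fixture(scope="session")
def synthetic_medium():
    """Seeded mid-size synthetic dataset with ground truth (shared, read-only)."""
    cfg = SyntheticConfig(n_entries=600, seed=11)
    return simulate_dataset(cfg)
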