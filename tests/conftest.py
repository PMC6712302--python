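import pytest

from neogut.synthio import SimConfig, simulate_dataset, write_dataset

#: Ledger label -> label the presence/absence classifier should assign.
#: Transferred families are recipient-unique from the fungal point of view
#: (their other copies sit in non-fungal kingdoms), so they classify as
#: unique_recipient; the similarity screen is what tells them apart.
EXPECTED_LABEL = {
    "shared": "shared",
    "unique": "unique_recipient",
    "lost": "lost_recipient",
    "hgt": "unique_recipient",
}


@pytest.fixture(scope="session")
def small_cfg():
    """A small two-clade study: 6 recipients, 3 outgroups, 3 donor
    kingdoms, 40 families with 4 planted unique, 3 lost, 3 transferred."""
    return SimConfig(
        n_recipient_taxa=6,
        n_outgroup_taxa=3,
        n_donor_taxa={"bacteria": 2, "animal": 2, "plant": 2},
        n_families=40,
        n_planted_unique_domains=4,
        n_planted_lost_domains=3,
        n_planted_hgt=3,
        loss_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_paths(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("smalldata")
    return write_dataset(small_dataset, outdir)
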