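import pytest

from mosaictrace import simulate as sim


@pytest.fixture(scope="session")
def small_pair():
    """Desk-scale parental pair: 60 kbp chromosome + 20 kbp megaplasmid."""
    return sim.generate_parental_pair([60_000, 20_000], seed=1,
                                      n_specific_genes=4, gene_length=1500)


@pytest.fixture(scope="session")
def study_pair():
    """Default study-condition pair: 200 kbp + 50 kbp, 1/124 SNP density."""
    return sim.generate_parental_pair(seed=11)


@pytest.fixture(scope="session")
def marked_clone(small_pair):
    """One transjugant with fragments, marker, a transposition and a gene capture."""
    cassette_id, cassette_seq = sim.default_cassette()
    target = sim.pick_marker_target(small_pair, "megaplasmid")
    return sim.simulate_transjugant(
        small_pair, "A", {"chromosome": 4, "megaplasmid": 2},
        marker=(cassette_id, cassette_seq, target), transposition_count=1,
        gene_insertions=["sgB00"], seed=11, clone_id="T1")


@pytest.fixture(scope="session")
def cassette():
    return sim.default_cassette()
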