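import pytest

from lionmatch import CladeVocabulary, GeneticProfile, LCURecord, default_registry


@pytest.fixture(scope="session")
def vocab():
    return CladeVocabulary.default()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def make_lcu(vocab):
    """Factory for ad-hoc LCU records with sensible defaults."""

    counter = {"n": 0}

    def _make(
        nu,
        mt,
        *,
        countries=("TZ",),
        suture_zone=None,
        hybrid=False,
        metapop=False,
        extant=True,
        rec_id=None,
    ):
        counter["n"] += 1
        rec = LCURecord(
            id=rec_id or f"t{counter['n']:02d}",
            name=f"test unit {counter['n']}",
            countries=frozenset(countries),
            profile=GeneticProfile(mtdna=frozenset(mt), nudna=frozenset(nu)),
            suture_zone=suture_zone,
            hybrid_origin=hybrid,
            managed_metapopulation=metapop,
            extant=extant,
        )
        rec.validate(vocab)
        return rec

    return _make
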