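import warnings

import numpy as np
import pytest

import flankact as fa


@pytest.fixture(scope="session")
def property_table():
    return fa.synthetic_property_table(n_properties=125, seed=13)


@pytest.fixture(scope="session")
def reduced_table(property_table):
    return fa.reduce_property_table(property_table)


@pytest.fixture(scope="session")
def small_library():
    return fa.synthetic_motif_library(seed=11)


@pytest.fixture(scope="session")
def worked():
    return fa.worked_fixture()


@pytest.fixture(scope="session")
def small_study():
    """Planted 48-record study small enough for fast full-model training."""
    spec = fa.SyntheticSpec(
        n_chromosomes=2,
        chrom_length=1_700_000,
        n_genes=48,
        distance_range=(100, 20_000),
        seed=5,
    )
    return fa.generate_study(spec)


@pytest.fixture(scope="session")
def small_records(small_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regs = small_study.region_sequences()
    labels = small_study.label_map()
    rids = sorted(regs)
    return rids, [regs[r] for r in rids], [labels[r] for r in rids]


@pytest.fixture(scope="session")
def tiny_model(small_study, small_records, reduced_table):
    """A fully trained two-layer model on the small planted study."""
    _, recs, labs = small_records
    library = fa.synthetic_motif_library(seed=small_study.spec.seed)
    cfg = fa.RunConfig(seed=5)
    enc = fa.Encoder(library, reduced_table, cfg)
    model = fa.TwoLayerModel(encoder=enc, config=cfg, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(recs, labs)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(20240615)
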