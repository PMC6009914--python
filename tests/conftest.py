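import numpy as np
import pytest

import qsar3d as q


@pytest.fixture(scope="session")
def records():
    return q.load_benchmark()


@pytest.fixture(scope="session")
def prepared_benchmark():
    """Embedded, charged, field-fit aligned benchmark (expensive; shared)."""
    return q.prepare_benchmark()


@pytest.fixture(scope="session")
def benchmark_results(prepared_benchmark):
    """Fitted CoMFA / region-focused / similarity-index models."""
    recs, mols = prepared_benchmark
    return {
        name: q.fit_benchmark_model(recs, mols, name)
        for name in ("comfa", "comfarf", "comsia")
    }


@pytest.fixture(scope="session")
def synthetic_default():
    from qsar3d.synthetic import SyntheticSpec, generate_synthetic

    return generate_synthetic(SyntheticSpec(n_compounds=20, noise_sd=0.1, seed=11))


@pytest.fixture(scope="session")
def mol26(records):
    rec = next(r for r in records if r.compound_id == 26)
    return q.assign_partial_charges(q.embed_and_minimize(rec.smiles, seed=7))


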