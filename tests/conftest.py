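import numpy as np
import pytest

import factalign as fa


@pytest.fixture(scope="session")
def toy_tables():
    """Tables trained on a small simulated homolog set (uncalibrated)."""
    chains, aligned = fa.make_training_set(10, fa.SimParams(seed=11))
    return fa.train_tables(chains, aligned, seed=11)


@pytest.fixture(scope="session")
def toy_db():
    """Small labelled benchmark set: 6 families x 3 members."""
    return fa.make_benchmark_set(6, 3, fa.SimParams(seed=12))


@pytest.fixture(scope="session")
def calibrated_tables(toy_db):
    """Freshly trained tables calibrated on the toy benchmark."""
    chains, aligned = fa.make_training_set(10, fa.SimParams(seed=11))
    tables = fa.train_tables(chains, aligned, seed=11)
    db, _ = toy_db
    fa.calibrate(db, tables)
    return tables


@pytest.fixture()
def helix30():
    """A clean 30-residue helix for geometric oracles."""
    p = fa.SimParams(seed=5, segment_spec=[("helix", 30)])
    return fa.synth_chain(p, id="helix30")


def collinear_chain(n=8, step=3.8, aa=None):
    coords = np.column_stack([step * np.arange(n), np.zeros(n), np.zeros(n)])
    return fa.ChainStructure(id="line", aa=aa or "A" * n, coords=coords)


@pytest.fixture()
def line8():
    return collinear_chain(8)
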