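import numpy as np
import pytest

from ribocontrast.datamodel import CountMatrix
from ribocontrast.quant import compute_rpkm, compute_te, normalize_libraries
from ribocontrast.simulate import (
    SimConfig,
    generate_transcriptome,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=150, seed=11, library_size=500_000)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genes, truth = generate_transcriptome(small_config)
    fp, tot = simulate_counts(genes, truth, small_config)
    return {"config": small_config, "genes": genes, "truth": truth, "fp": fp, "tot": tot}


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    fp, tot = small_dataset["fp"], small_dataset["tot"]
    combined = CountMatrix(
        genes=list(fp.genes),
        libraries=fp.libraries + tot.libraries,
        counts=np.hstack([fp.counts, tot.counts]),
    )
    expr = compute_rpkm(combined, small_dataset["genes"])
    expr = normalize_libraries(expr, "median-ratio")
    return compute_te(expr)
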