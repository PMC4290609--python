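import logging

import numpy as np
import pandas as pd
import pytest

import pcafe
from pcafe.simulate import SimConfig

logging.getLogger("pcafe").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_default():
    """The default synthetic study (seed 0): paired expression/methylation
    matrices with planted cell-line and metastasis gene sets."""
    return pcafe.generate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def summary_default(sim_default):
    """Full integrated analysis of the default synthetic study."""
    d = sim_default
    return pcafe.integrated_analysis(d.expr, d.meth, d.annot_expr, d.annot_meth)


@pytest.fixture(scope="session")
def sim_small():
    """A scaled-down synthetic study for file-based smoke tests."""
    return pcafe.generate(SimConfig(n_genes=300, n_cellline_genes=30,
                                    n_metH_genes=15, n_metA_genes=10, seed=1))


def make_matrix(values, sample_specs, platform="test", probe_prefix="P", is_beta=False):
    """Build an OmicsMatrix from a raw array and (cell_line, metastasis,
    replicate) sample specs."""
    values = np.asarray(values, float)
    design = {}
    sample_ids = []
    for i, (cell, met, rep) in enumerate(sample_specs):
        sid = f"S{i + 1}_{cell}_{met}_{rep}"
        design[sid] = pcafe.SampleDesign(cell, met, rep)
        sample_ids.append(sid)
    probes = [f"{probe_prefix}{i + 1}" for i in range(values.shape[0])]
    return pcafe.OmicsMatrix(
        platform_id=platform,
        values=pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                            columns=sample_ids),
        design=design,
        is_beta=is_beta,
    )


def balanced_specs(replicates):
    """Sample specs covering all four design categories."""
    specs = []
    for cell in ("A549", "HTB56"):
        for met in ("without", "with"):
            for r in range(1, replicates + 1):
                specs.append((cell, met, r))
    return specs


@pytest.fixture
def matrix_2x2():
    """8-sample random matrix over the full design, 2 replicates/category."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(5, 1, (60, 8)), balanced_specs(2))
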