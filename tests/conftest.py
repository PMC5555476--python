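import numpy as np
import pandas as pd
import pytest

from crisprscreen import (
    FoldchangeMatrix,
    NormalizationParams,
    ReadcountMatrix,
    ReferenceSets,
    compute_foldchange,
)


def make_fcm(values, genes, replicate_names=None):
    """FoldchangeMatrix from a guide->list-of-fc mapping and guide->gene map."""
    fc = pd.DataFrame(
        {g: np.atleast_1d(v) for g, v in values.items()}
    ).T
    fc.columns = replicate_names or [f"R{i + 1}" for i in range(fc.shape[1])]
    gene = pd.Series(genes).reindex(fc.index)
    return FoldchangeMatrix(fc=fc.astype(float), gene_of_guide=gene)


@pytest.fixture
def fcm_factory():
    return make_fcm


@pytest.fixture
def two_guide_rc():
    """The hand-arithmetic normalization example: T0 [100,100], endpoint [100,0]."""
    return ReadcountMatrix(
        counts=pd.DataFrame({"T0": [100, 100], "R1": [100, 0]},
                            index=["g1", "g2"]),
        gene_of_guide=pd.Series(["GA", "GB"], index=["g1", "g2"]),
        sample_roles={"T0": "t0_control", "R1": "endpoint"},
    )


@pytest.fixture(scope="session")
def normal_training_fcm():
    """Large KDE training set: 500 essential genes ~N(-3,1), 500 nonessential
    ~N(0,1), ten guides each, plus a probe gene with four guides at fc=-3."""
    rng = np.random.default_rng(7)
    guides, fcv, gmap = [], [], []
    for cls, mu in (("ESS", -3.0), ("NON", 0.0)):
        for i in range(500):
            for j in range(10):
                guides.append(f"{cls}{i}_{j}")
                fcv.append(rng.normal(mu, 1.0))
                gmap.append(f"{cls}{i}")
    for j in range(4):
        guides.append(f"PROBE_{j}")
        fcv.append(-3.0)
        gmap.append("PROBE")
    fcm = FoldchangeMatrix(
        fc=pd.DataFrame({"R1": fcv}, index=guides),
        gene_of_guide=pd.Series(gmap, index=guides),
    )
    refs = ReferenceSets({f"ESS{i}" for i in range(500)},
                         {f"NON{i}" for i in range(500)})
    return fcm, refs


@pytest.fixture(scope="session")
def resample_invariant_fcm():
    """Training set where every gene of a class has identical guide fold-changes,
    so gene bootstrap leaves the KDE training pools unchanged each iteration."""
    guides, fcv, gmap = [], [], []
    ess_vals = np.linspace(-5, -1, 9)
    non_vals = np.linspace(-2, 2, 9)
    for cls, vals in (("ESS", ess_vals), ("NON", non_vals)):
        for i in range(25):
            for j, v in enumerate(vals):
                guides.append(f"{cls}{i}_{j}")
                fcv.append(v)
                gmap.append(f"{cls}{i}")
    fcm = FoldchangeMatrix(
        fc=pd.DataFrame({"R1": fcv}, index=guides),
        gene_of_guide=pd.Series(gmap, index=guides),
    )
    refs = ReferenceSets({f"ESS{i}" for i in range(25)},
                         {f"NON{i}" for i in range(25)})
    return fcm, refs


def add_probe_genes(fcm, probes):
    """Return a copy of ``fcm`` with extra genes (gene -> list of fc values)."""
    guides, fcv, gmap = [], [], []
    for gene, vals in probes.items():
        for j, v in enumerate(np.atleast_1d(vals)):
            guides.append(f"{gene}_{j}")
            fcv.append(float(v))
            gmap.append(gene)
    extra_fc = pd.DataFrame({"R1": fcv}, index=guides)
    extra_gene = pd.Series(gmap, index=guides)
    return FoldchangeMatrix(
        fc=pd.concat([fcm.fc, extra_fc]),
        gene_of_guide=pd.concat([fcm.gene_of_guide, extra_gene]),
    )
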