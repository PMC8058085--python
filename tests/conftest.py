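"""Shared fixtures: one well-specified (Weibull, theta = 1) reference study
fitted once per session and reused by the calibration, effect-size and
coverage checks."""

import numpy as np
import pytest

from bayesw.core import HyperParams, SurvivalData
from bayesw.gibbs import GibbsConfig, GroupLayout, PosteriorSamples, gibbs_serial
from bayesw.simulate import SimDesign, simulate_dataset
from bayesw.sparse import GenotypeMatrix


@pytest.fixture(scope="session")
def reference_study():
    """theta=1, h2=0.5 study: 2000 training + 1000 held-out individuals,
    5000 markers, 50 causal; two chains of 2000 iterations (burn-in 1000,
    thinning 5) with slab constants {0.001, 0.01}."""
    design = SimDesign(n_individuals=3000, n_markers=5000, n_causal=50,
                       heritability=0.5, theta=1.0, seed=101)
    data_all, X_all, truth = simulate_dataset(design)
    counts = np.column_stack([X_all.counts_col(j)
                              for j in range(X_all.n_markers)])
    X_train = GenotypeMatrix.from_counts(counts[:2000], X_all.markers)
    X_test = GenotypeMatrix.from_counts(counts[2000:], X_all.markers)
    data_train = SurvivalData(log_time=data_all.log_time[:2000],
                              failure=data_all.failure[:2000],
                              trunc_age=np.zeros(2000),
                              covariates=np.zeros((2000, 0)))
    layout = GroupLayout.single_group(5000, (0.001, 0.01))
    chains = []
    for chain_id in range(2):
        cfg = GibbsConfig(iterations=2000, burn_in=1000, thinning=5,
                          seed=1, chain_id=chain_id)
        chains.append(gibbs_serial(data_train, X_train, HyperParams(),
                                   layout, cfg))
    samples = PosteriorSamples.concatenate(chains)
    return {
        "samples": samples,
        "truth": truth,
        "X_train": X_train,
        "X_test": X_test,
        "data_train": data_train,
        "test_slice": slice(2000, 3000),
    }
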