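"""Shared fixtures: small maps, a compact cross design, and one default cross.

The default-design fixtures are session-scoped because simulating a
491-mouse, ~2,000-marker cross and smoothing its genotype probabilities
is the expensive part of the suite; every test that only reads them can
share one instance.
"""

import numpy as np
import pandas as pd
import pytest

from qtlmediate import (
    ChromSpec, MarkerMap, PipelineConfig, SimDesign, calc_genoprob,
    encode_covariates, normal_quantile_transform, run_pipeline, simulate_cross,
)


def enumerate_posterior(obs, cm, eps):
    """Exhaustive-path posterior genotype probabilities for one mouse.

    Independent oracle for the forward-backward smoother: sums the joint
    probability of every possible hidden-genotype path over the chromosome
    (3^L paths), weighting by the 1:2:1 prior, Haldane/F2 transition
    probabilities, and the noisy-call emission model.
    """
    from itertools import product

    prior = np.array([0.25, 0.5, 0.25])
    L = len(cm)
    r = 0.5 * (1.0 - np.exp(-2.0 * np.diff(np.asarray(cm, dtype=float)) / 100.0))

    def trans(rf):
        s, t = 1 - rf, rf
        return np.array([[s * s, 2 * s * t, t * t],
                         [s * t, s * s + t * t, s * t],
                         [t * t, 2 * s * t, s * s]])

    T = [trans(rf) for rf in r]

    def emit(o, state):
        if np.isnan(o):
            return 1.0
        return 1.0 - eps if int(o) == state else eps / 2.0

    post = np.zeros((L, 3))
    total = 0.0
    for path in product(range(3), repeat=L):
        p = prior[path[0]] * emit(obs[0], path[0])
        for k in range(1, L):
            p *= T[k - 1][path[k - 1], path[k]] * emit(obs[k], path[k])
        total += p
        for k in range(L):
            post[k, path[k]] += p
    return post / total


def single_chrom_map(length_cm=100.0, n_markers=11, chrom="1", length_mbp=None):
    cm = np.linspace(0.0, length_cm, n_markers)
    mbp = cm * ((length_mbp or length_cm * 1.5) / length_cm)
    return MarkerMap(pd.DataFrame({
        "chrom": chrom, "marker": [f"c{chrom}m{i}" for i in range(n_markers)],
        "cM": cm, "Mbp": mbp, "pseudo": False}))


@pytest.fixture
def chr_map():
    return single_chrom_map()


def compact_design(seed=0, **kw):
    """A 4-chromosome design small enough for per-test simulation."""
    defaults = dict(
        n_mice=300,
        chromosomes=[ChromSpec("1", 80.0, 120.0, 41), ChromSpec("2", 100.0, 180.0, 51),
                     ChromSpec("3", 70.0, 110.0, 36), ChromSpec("4", 60.0, 90.0, 31)],
        n_mediated=8, n_direct=2, n_decoy_cis=6, n_null=10,
        seed=seed,
    )
    defaults.update(kw)
    return SimDesign(**defaults)


@pytest.fixture(scope="session")
def default_cross():
    return simulate_cross(SimDesign(seed=7))


@pytest.fixture(scope="session")
def default_gp(default_cross):
    return calc_genoprob(default_cross.geno, default_cross.marker_map)


@pytest.fixture(scope="session")
def default_covars(default_cross):
    return encode_covariates(default_cross.covar)


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    cfg = PipelineConfig(simulate=True, seed=7,
                         outdir=str(tmp_path_factory.mktemp("pipeline")),
                         log_level="WARNING", design=SimDesign(seed=7))
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_transformed(default_cross):
    ph = default_cross.pheno
    return pd.DataFrame({t: normal_quantile_transform(ph[t]) for t in ph.columns},
                        index=ph.index)
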