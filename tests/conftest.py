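"""Shared fixtures: the study-scale architecture, neutral thresholds, and
model ensembles reused across parallelism and acceptance tests.

Ensemble fixtures share one seed so paired (common-random-number) model
comparisons are possible; all are session-scoped because each costs minutes
of Wright-Fisher simulation.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erparallel.architecture import ExperimentDesign, gen_architecture
from erparallel.fitness import FitnessModel
from erparallel.parallelism import default_thresholds, simulate_parallelism

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# ensemble size for study-scale simulations: large enough that the Monte
# Carlo SE of the ensemble mean Jaccard (~0.002) is far below the tolerances
# tested, small enough to keep the suite fast
N_ENSEMBLE = 100
ENSEMBLE_SEED = 5
ALPHA_HAT = 36.5  # epistasis strength matching the empirical parallelism


@pytest.fixture(scope="session")
def arch121():
    return gen_architecture(121, seed=3)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def thresholds121(arch121, design):
    return default_thresholds(arch121, design, seed=11)


def _ensemble(arch, design, model, thresholds, **kw):
    return simulate_parallelism(
        arch, design, model, n_iter=N_ENSEMBLE, seed=ENSEMBLE_SEED,
        thresholds=thresholds, **kw,
    )


@pytest.fixture(scope="session")
def mult_ensemble(arch121, design, thresholds121):
    return _ensemble(arch121, design, FitnessModel(kind="multiplicative"),
                     thresholds121)


@pytest.fixture(scope="session")
def epi_ensemble(arch121, design, thresholds121):
    return _ensemble(
        arch121, design,
        FitnessModel(kind="positive_epistasis", alpha=ALPHA_HAT), thresholds121,
    )


# smaller ensembles (one per fitness model, common seed) for the
# across-model sensitivity comparisons
N_MODEL_ENSEMBLE = 60


@pytest.fixture(scope="session")
def qt_ensembles(arch121, design, thresholds121):
    from erparallel.fitness import reconstruct_qt_params

    out = {}
    for kind in ("shifted_optimum", "directional", "truncating"):
        model = reconstruct_qt_params(arch121, kind)
        out[kind] = simulate_parallelism(
            arch121, design, model, n_iter=N_MODEL_ENSEMBLE,
            seed=ENSEMBLE_SEED, thresholds=thresholds121,
        )
    return out


def mean_jaccard(ensemble, generation):
    sub = ensemble[ensemble["generation"] == generation]
    return float(sub["mean_jaccard"].mean())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
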