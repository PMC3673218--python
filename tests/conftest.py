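import numpy as np
import pytest

from hmmdriver import (
    AssignmentStore,
    BackgroundComposition,
    DomainAssignment,
    DriverMutationModel,
    ModelRegistry,
    ModelSource,
    ProfileHMM,
    SyntheticScenario,
    generate_scenario,
)
from hmmdriver.alphabet import N_AMINO_ACIDS


def make_profile(model_id, emissions, background=None):
    """ProfileHMM from a (length, 20) array, rows renormalised."""
    e = np.asarray(emissions, dtype=float)
    e = e / e.sum(axis=1, keepdims=True)
    bg = background if background is not None else BackgroundComposition.default().probabilities
    return ProfileHMM(model_id=model_id, source=ModelSource.AB_INITIO, emissions=e, background=bg)


def peaked_column(peak_index, peak=0.8):
    """An emission column concentrated on one residue."""
    col = np.full(N_AMINO_ACIDS, (1.0 - peak) / (N_AMINO_ACIDS - 1))
    col[peak_index] = peak
    return col


@pytest.fixture(scope="session")
def background():
    return BackgroundComposition.default()


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted-structure study (seed 7, 4 models, 500/class)."""
    return generate_scenario(SyntheticScenario())


@pytest.fixture(scope="session")
def fitted(default_bundle):
    b = default_bundle
    return DriverMutationModel(b.variants, b.assignments, b.registry).fit()


@pytest.fixture()
def toy_registry(background):
    """Three tiny models: flat (KL~0), peaked, and intermediate."""
    bgv = background.probabilities
    flat = make_profile("FLAT", np.tile(bgv, (3, 1)))
    peaked = make_profile("PEAK", np.vstack([peaked_column(0), peaked_column(5), peaked_column(10)]))
    mid = make_profile(
        "MID", np.vstack([0.5 * bgv + 0.5 * peaked_column(0, 0.5)] * 3)
    )
    return ModelRegistry([flat, peaked, mid])


def simple_assignment(protein_id="P1", model_id="PEAK", e_value=1e-4, seq_start=1, hmm_start=1, ops="MMM"):
    return DomainAssignment(
        protein_id=protein_id, model_id=model_id, e_value=e_value,
        seq_start=seq_start, hmm_start=hmm_start, ops=ops,
    )


@pytest.fixture()
def toy_assignments():
    return AssignmentStore(
        [simple_assignment("P1", "PEAK"), simple_assignment("P2", "FLAT"), simple_assignment("P2", "MID")]
    )
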