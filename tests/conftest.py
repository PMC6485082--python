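import numpy as np
import pytest

from coaldelim import (
    AlignedLocus,
    MCMCSettings,
    PopulationMap,
    SimulationSpec,
    simulate_dataset,
)
from coaldelim.priors import InverseGammaPrior, PriorSet


@pytest.fixture
def tiny_locus():
    return AlignedLocus(
        name="tiny",
        samples=("s1", "s2", "s3", "s4"),
        sequences=("ACGTACGTAA", "ACGTACGTAT", "ACGAACGTTT", "ACGAACTTTT"),
    )


@pytest.fixture
def tiny_popmap():
    return PopulationMap({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture
def default_priors():
    return PriorSet(
        InverseGammaPrior(3, 0.002), InverseGammaPrior(3, 0.004), "default"
    )


@pytest.fixture
def short_settings():
    """Chain lengths sized for unit tests, not production runs."""
    return MCMCSettings(samples=400, burnin=200, thin=2)


@pytest.fixture
def split_dataset():
    """One simulated dataset with a clear divergence (tau = 5 * theta)."""
    spec = SimulationSpec(tau=0.01, seed=11)
    locus, popmap, truth = simulate_dataset(spec)
    return locus, popmap, truth


def random_locus(rng: np.random.Generator, n: int, length: int) -> AlignedLocus:
    """Random alignment with occasional gaps/ambiguities for oracle tests."""
    alphabet = np.array(list("ACGT" * 5 + "N-RY"))
    seqs = tuple(
        "".join(rng.choice(alphabet, size=length)) for _ in range(n)
    )
    return AlignedLocus(
        name="rand",
        samples=tuple(f"s{i}" for i in range(n)),
        sequences=seqs,
    )
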