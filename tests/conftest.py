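import numpy as np
import pytest

from kinfam.pipeline import run_survey
from kinfam.simulate import FamilySimConfig, simulate_all

SIM_SEED = 101


@pytest.fixture(scope="session")
def sim_truth(tmp_path_factory):
    """Default synthetic dataset: 40 family members (20/12/8), 10 segmental
    + 3 tandem planted pairs, 5 intronless, 60 decoys."""
    out = tmp_path_factory.mktemp("sim")
    return simulate_all(FamilySimConfig(seed=SIM_SEED), out)


@pytest.fixture(scope="session")
def sim_report(sim_truth):
    """Survey report over the synthetic dataset."""
    return run_survey(sim_truth.files, seed=SIM_SEED, bootstrap_replicates=0)


def planted_motif_dataset(seed, n=30, length=100, motif="MAPEVLKHPW"):
    """Random protein sequences each carrying the motif with one mutation."""
    from kinfam.identify import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    seqs, sites = {}, {}
    for i in range(n):
        s = list("".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, size=length)))
        pos = int(rng.integers(0, length - len(motif) + 1))
        planted = list(motif)
        planted[int(rng.integers(len(motif)))] = AMINO_ACIDS[int(rng.integers(20))]
        s[pos:pos + len(motif)] = planted
        seqs[f"s{i}"] = "".join(s)
        sites[f"s{i}"] = pos
    return seqs, sites
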