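import numpy as np
import pandas as pd
import pytest

from mitoamt import synthetic


@pytest.fixture(scope="session")
def small_truth():
    return synthetic.generate_ground_truth(
        n_proteins=40, peptides_per_protein=(3, 6), de_fraction=0.25, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    """A compact noisy cohort (4v4 x 2 replicates) with its manifest."""
    design = synthetic.CohortDesign(n_per_group=4, n_replicates=2)
    noise = synthetic.NoiseModel(seed=5, id_rate=0.3)
    runs, sheet, manifest = synthetic.simulate_cohort(small_truth, design, noise)
    return runs, sheet, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_run_features(masses, elutions, intensities=None, peptide_ids=None,
                      run_id="run1"):
    """Hand-build a UMC feature table for unit tests."""
    n = len(masses)
    return pd.DataFrame(
        {
            "run_id": run_id,
            "umc_id": [f"{run_id}_u{i}" for i in range(n)],
            "monoisotopic_mass_da": masses,
            "elution_scan": elutions,
            "intensity": intensities if intensities is not None else [1e6] * n,
            "charge": 2,
            "peptide_id": peptide_ids if peptide_ids is not None else [""] * n,
        }
    )
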