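import numpy as np
import pytest

from deepsubtype.synthdata import CohortConfig, LatentHierarchy, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-tissue, three-subtype cohort used across modules."""
    return generate_cohort(CohortConfig(
        n_tissues=2, tumors_per_tissue=45, controls_per_tissue=20,
        n_genes=90, n_subtypes=3,
        hierarchy=LatentHierarchy.balanced(90), seed=123))


@pytest.fixture(scope="session")
def factorial_cohort_builder():
    """Cohort whose binarized tumors are driven by ~independent TF bits:
    many subtypes over a one-TF-per-pathway-per-process hierarchy."""
    def build(seed, n_genes=120, n_tfs=8, tumors=160, effect_size=6.0,
              n_subtypes=48):
        hier = LatentHierarchy.balanced(
            n_genes, n_tfs=n_tfs, n_pathways=n_tfs, n_processes=n_tfs,
            signal_fraction=1.0, effect_size=effect_size)
        return generate_cohort(CohortConfig(
            n_tissues=1, tumors_per_tissue=tumors, controls_per_tissue=40,
            n_genes=n_genes, n_subtypes=n_subtypes, hierarchy=hier,
            cnv_rate=0.0, seed=seed))
    return build


def pearson(x, y):
    """Brute-force Pearson correlation used as an oracle in several tests."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    return float((xm * ym).sum() / denom)
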