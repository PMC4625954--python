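import numpy as np
import pytest

from cgimeth import SimConfig, build_profiles, mean_signature, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_samples_normal=30, n_samples_cancer=40, n_cgi=40,
                     n_regulated_genes=4, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    """Cancer-condition profiles of the small cohort."""
    c = small_cohort
    return build_profiles(c.beta_cancer, c.manifest.probes,
                          annotation=c.manifest.genes,
                          islands=c.manifest.islands)


def island_mean_levels(profiles, signatures):
    """Mean island beta per signature, used for canonical cluster labeling."""
    out = []
    for p, s in zip(profiles, signatures):
        mask = np.array([r == "island" for r in p.regions])
        out.append(float(np.mean(s.Y[mask])) if mask.any() else float(np.mean(s.Y)))
    return np.asarray(out)


def signatures_of(profiles, condition=""):
    return [mean_signature(p, condition=condition) for p in profiles]
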