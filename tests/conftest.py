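import warnings

import numpy as np
import pytest

from cgprofiler.calibration import cohort_metrics
from cgprofiler.simulate import GeneratorConfig, generate_cohort

#: reduced cohort for fast unit tests; not the study conditions
SMALL_KWARGS = dict(
    group_sizes={"African": 25, "European": 60, "EastAsian": 25, "Other": 8},
    n_genes=30,
    gene_type_counts={"tumor_suppressor": 12, "oncogene": 10, "predisposition": 8},
    n_flips=4,
    n_reference_minor=3,
    group_specific_counts={"African": 3},
    n_nonsense=4,
    n_frameshift=6,
    n_splice=3,
    n_inframe=2,
    n_deleterious_common=3,
    n_low_callrate_sites=4,
    n_low_fracdepth_sites=4,
    panel_markers=400,
    target_mean_load=20.0,
)


@pytest.fixture(scope="session")
def default_syn():
    """One full-size synthetic cohort under the default study conditions."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_metrics(default_syn):
    """Filtered + annotated + profiled view of the default cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort_metrics(default_syn)


@pytest.fixture(scope="session")
def small_syn():
    return generate_cohort(GeneratorConfig(seed=3, **SMALL_KWARGS))


@pytest.fixture()
def rng():
    return np.random.default_rng(20140411)
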