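import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from tcrbalance.burden import BalanceParams
from tcrbalance.repertoire import Clonotype, RepertoireSample


@pytest.fixture
def default_params():
    """Whole-body estimates: N=6e11, M=1e10, T=7e11, lifetimes 6.6/3.5 d."""
    return BalanceParams()


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_sample(read_counts, kind="end_of_trial_bm", locus="beta", patient="P1",
                prefix="CASS", **kwargs):
    """Small sample with distinct valid CDR3s and the given read counts."""
    clones = [
        Clonotype(
            locus=locus,
            cdr3_aa=f"{prefix}{AA20[i // 20]}{AA20[i % 20]}F",
            read_count=int(rc),
        )
        for i, rc in enumerate(read_counts)
    ]
    return RepertoireSample(
        patient_id=patient, sample_kind=kind, locus=locus, clonotypes=clones, **kwargs
    )


@pytest.fixture
def toy_sample():
    return make_sample([5, 3, 1])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
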