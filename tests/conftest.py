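from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from aquafam.align import progressive_msa
from aquafam.phylo import bootstrap_support
from aquafam.synth import FamilyConfig, generate_family

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def family():
    """The default study-sized synthetic family (47 members + 200 decoys)."""
    return generate_family(FamilyConfig(seed=1))


@pytest.fixture(scope="session")
def family_members(family):
    truth = family.truth
    return [p for p in family.proteome if not truth[p.id].is_decoy]


@pytest.fixture(scope="session")
def family_tree(family, family_members):
    """Bootstrapped NJ tree over all members plus the reference panel."""
    msa = progressive_msa(family_members + family.panel.proteins)
    return msa, bootstrap_support(msa, n=100, seed=7)
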