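"""Shared fixtures: small deterministic simulations reused across tests."""

import pytest

from backsplice.detect import DetectorConfig
from backsplice.pipeline import detect_bundle, simulate_bundle
from backsplice.simulate import SimConfig


@pytest.fixture(scope="session")
def default_bundle():
    """The package's default study conditions: 20 genes, 10 planted
    circRNAs, ~50k read pairs, error rate 0."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_records(default_bundle):
    return detect_bundle(default_bundle, apply_filter=False)


@pytest.fixture(scope="session")
def small_bundle():
    """A lean simulation with fractions and regulatory sites for the
    downstream stages."""
    config = SimConfig(
        seed=7,
        n_read_pairs=6_000,
        n_fraction_read_pairs=6_000,
        circ_pairs_min=60,
        circ_pairs_max=90,
    )
    return simulate_bundle(
        config, with_fractions=True, with_netseq=True, with_regulatory=True
    )


@pytest.fixture(scope="session")
def small_records(small_bundle):
    return detect_bundle(small_bundle, DetectorConfig(max_mismatches=0))
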