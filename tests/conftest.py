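import numpy as np
import pytest

from mockbarcode.community import (
    TREATMENT_PRESETS,
    CommunitySpec,
    PlatformProfile,
    generate_community,
    simulate_amplicon_pool,
    simulate_template_pool,
)


@pytest.fixture(scope="session")
def small_community():
    """20-species community, fixed seed, reused read-only across tests."""
    return generate_community(CommunitySpec(n_species=20, seed=11))


@pytest.fixture(scope="session")
def small_library(small_community):
    return [(sp.bin_id, sp.barcode_seq) for sp in small_community]


@pytest.fixture(scope="session")
def biased_shares(small_community):
    model = TREATMENT_PRESETS["bulk_abdomen"]
    templates = simulate_template_pool(small_community, model, seed=3)
    mismatches = np.array(
        [sp.fwd_mismatches + sp.rev_mismatches for sp in small_community])
    return simulate_amplicon_pool(templates, mismatches, model)


@pytest.fixture(scope="session")
def clean_paired_profile():
    """Error-free MiSeq-like profile (deterministic read content)."""
    return PlatformProfile("miseq_like", read_length_mean=250, read_length_sd=0,
                           qv_start=35, qv_slope=0.0, sub_rate=0.0,
                           indel_rate=0.0, paired=True)


@pytest.fixture(scope="session")
def clean_single_profile():
    """Error-free single-end profile spanning the whole 437 bp amplicon."""
    return PlatformProfile("s5_like", read_length_mean=437, read_length_sd=0,
                           qv_start=34, qv_slope=-0.02, sub_rate=0.0,
                           indel_rate=0.0, paired=False)
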