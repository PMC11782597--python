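import numpy as np
import pytest

from protscreen import AssociationRecord, SummaryStatSet, VariantKey


def make_record(
    rsid="rs1", chrom="1", pos=100, ea="A", oa="G",
    beta=0.1, se=0.05, pval=1e-4, eaf=0.3, n=10_000.0,
    n_case=None, n_control=None,
):
    return AssociationRecord(
        VariantKey(rsid, chrom, pos, ea, oa),
        beta=beta, se=se, pval=pval, eaf=eaf, n=n,
        n_case=n_case, n_control=n_control,
    )


def make_set(records, trait_id="trait", trait_type="quantitative"):
    sset = SummaryStatSet(trait_id, trait_type)
    for rec in records:
        sset.add(rec)
    return sset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shared_causal_bundle():
    """One default shared-causal scenario bundle, reused across tests."""
    from protscreen import SyntheticTruth, simulate_scenario

    return simulate_scenario(SyntheticTruth.for_scenario("shared_causal", seed=11))
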