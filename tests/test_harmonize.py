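"""Allele alignment: swaps, strand flips, palindromes, proxies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protscreen import (
    HarmonizeConfig,
    LDMatrix,
    find_proxy,
    harmonize_instrument,
    harmonize_pair,
    ld_from_haplotypes,
)

from conftest import make_record, make_set


def test_direct_match():
    exp = make_record("rs1", ea="A", oa="G", beta=0.2, eaf=0.3)
    out = make_record("rs1", ea="A", oa="G", beta=0.1, eaf=0.3)
    row = harmonize_pair(exp, out)
    assert row.action == "direct"
    assert row.beta_x == 0.2 and row.beta_y == 0.1


def test_swapped_alleles_flip_outcome():
    exp = make_record("rs1", ea="A", oa="G", beta=0.2, eaf=0.3)
    out = make_record("rs1", ea="G", oa="A", beta=0.1, eaf=0.7)
    row = harmonize_pair(exp, out)
    assert row.action == "flipped"
    assert row.beta_y == -0.1
    assert row.eaf_y == pytest.approx(0.3)


def test_complement_strand_flip():
    exp = make_record("rs1", ea="A", oa="G", beta=0.2)
    out = make_record("rs1", ea="T", oa="C", beta=0.1)  # same SNP, other strand
    row = harmonize_pair(exp, out)
    assert row.action == "direct" and row.beta_y == 0.1


def test_swapped_complement():
    exp = make_record("rs1", ea="A", oa="G", beta=0.2, eaf=0.3)
    out = make_record("rs1", ea="C", oa="T", beta=0.1, eaf=0.7)
    row = harmonize_pair(exp, out)
    assert row.action == "flipped" and row.beta_y == -0.1


def test_incompatible_alleles_dropped():
    exp = make_record("rs1", ea="A", oa="G")
    out = make_record("rs1", ea="A", oa="C")
    row = harmonize_pair(exp, out)
    assert row.action == "dropped" and row.drop_reason == "incompatible_alleles"


def test_exposure_oriented_to_increasing_allele():
    exp = make_record("rs1", ea="A", oa="G", beta=-0.2, eaf=0.3)
    out = make_record("rs1", ea="A", oa="G", beta=0.1, eaf=0.3)
    row = harmonize_pair(exp, out)
    assert row.beta_x == 0.2 and row.beta_y == -0.1
    assert row.eaf == pytest.approx(0.7)


def test_rsid_mismatch_raises():
    with pytest.raises(ValueError):
        harmonize_pair(make_record("rs1"), make_record("rs2"))


# --- palindromic SNPs ---


def test_palindrome_opposite_freq_sides_inferred_and_flipped():
    exp = make_record("rs1", ea="A", oa="T", beta=0.2, eaf=0.1)
    out = make_record("rs1", ea="A", oa="T", beta=0.1, eaf=0.88)
    row = harmonize_pair(exp, out)
    assert row.action == "strand_inferred"
    assert row.beta_y == pytest.approx(-0.1)
    assert row.eaf_y == pytest.approx(0.12)


def test_palindrome_same_freq_side_kept_as_is():
    exp = make_record("rs1", ea="C", oa="G", beta=0.2, eaf=0.1)
    out = make_record("rs1", ea="C", oa="G", beta=0.1, eaf=0.15)
    row = harmonize_pair(exp, out)
    assert row.action == "strand_inferred" and row.beta_y == pytest.approx(0.1)


def test_palindrome_high_maf_dropped():
    exp = make_record("rs1", ea="A", oa="T", beta=0.2, eaf=0.45)
    out = make_record("rs1", ea="A", oa="T", beta=0.1, eaf=0.52)
    row = harmonize_pair(exp, out)
    assert row.action == "dropped" and row.drop_reason == "ambiguous_palindrome"


def test_palindrome_orientation_truth_table():
    """Enumerate label/strand cases for a palindromic SNP with a known
    underlying alignment; the harmonized outcome beta must always recover
    the truth (outcome effect +0.1 on the exposure's effect allele)."""
    # underlying truth: effect allele A, exposure EAF 0.1, outcome beta +0.1
    cases = [
        # (out ea, out oa, out beta, out eaf) as labelled in the outcome study
        ("A", "T", 0.1, 0.12),    # same labels, same strand
        ("T", "A", -0.1, 0.88),   # swapped labels, same strand
        ("T", "A", 0.1, 0.12),    # other strand read: T is truth-A's partner
        ("A", "T", -0.1, 0.88),   # other strand and swapped
    ]
    for ea, oa, beta, eaf in cases:
        exp = make_record("rs1", ea="A", oa="T", beta=0.2, eaf=0.1)
        out = make_record("rs1", ea=ea, oa=oa, beta=beta, eaf=eaf)
        row = harmonize_pair(exp, out)
        assert row.action == "strand_inferred"
        assert row.beta_y == pytest.approx(0.1), (ea, oa, beta, eaf)


# --- properties ---


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    beta_x=st.floats(-1, 1).filter(lambda b: abs(b) > 1e-3),
    beta_y=st.floats(-1, 1),
    eaf=st.floats(0.05, 0.95),
    swap_out=st.booleans(),
)
def test_orientation_invariance_of_wald_ratio(beta_x, beta_y, eaf, swap_out):
    """Relabelling the exposure's alleles (negating beta, 1-EAF) must leave
    the implied Wald ratio unchanged."""
    out_alleles = ("G", "A") if swap_out else ("A", "G")
    out_beta = -beta_y if swap_out else beta_y
    out = make_record("rs1", ea=out_alleles[0], oa=out_alleles[1],
                      beta=out_beta, eaf=0.5)
    r1 = harmonize_pair(make_record("rs1", ea="A", oa="G", beta=beta_x, eaf=eaf), out)
    r2 = harmonize_pair(
        make_record("rs1", ea="G", oa="A", beta=-beta_x, eaf=1 - eaf), out)
    assert r1.beta_y / r1.beta_x == pytest.approx(r2.beta_y / r2.beta_x, rel=1e-9)
    assert r1.beta_x == pytest.approx(r2.beta_x)


def test_idempotence_on_aligned_records():
    exp = make_record("rs1", ea="A", oa="G", beta=0.2, eaf=0.3)
    out = make_record("rs1", ea="A", oa="G", beta=0.1, eaf=0.3)
    once = harmonize_pair(exp, out)
    again = harmonize_pair(
        exp.replace(beta=once.beta_x, eaf=once.eaf),
        out.replace(beta=once.beta_y, eaf=once.eaf_y),
    )
    assert (again.beta_x, again.beta_y, again.eaf) == (
        once.beta_x, once.beta_y, once.eaf)
    assert again.action == "direct"


def test_every_pair_maps_to_exactly_one_action():
    from protscreen.harmonize import ACTIONS

    exp = make_record("rs1", ea="A", oa="T", beta=0.2, eaf=0.45)
    out = make_record("rs1", ea="A", oa="T", beta=0.1, eaf=0.52)
    assert harmonize_pair(exp, out).action in ACTIONS


# --- proxies ---


def _ld_with_r(rsids, positions, r_pairs):
    m = len(rsids)
    r = np.eye(m)
    for (i, j), v in r_pairs.items():
        r[i, j] = r[j, i] = v
    return LDMatrix(rsids, r, positions)


def test_proxy_target_present_returns_identity():
    outcome = make_set([make_record("rs1")])
    ld = _ld_with_r(["rs1"], [100], {})
    match = find_proxy("rs1", outcome, ld)
    assert match.proxy_rsid == "rs1" and match.r == 1.0


def test_proxy_argmax_r2():
    outcome = make_set([
        make_record("rs2", pos=200), make_record("rs3", pos=300)])
    ld = _ld_with_r(["rs1", "rs2", "rs3"], [100, 200, 300],
                    {(0, 1): np.sqrt(0.85), (0, 2): np.sqrt(0.92)})
    match = find_proxy("rs1", outcome, ld)
    assert match.proxy_rsid == "rs3"


def test_no_qualifying_proxy_returns_none():
    outcome = make_set([make_record("rs2", pos=200)])
    ld = _ld_with_r(["rs1", "rs2"], [100, 200], {(0, 1): 0.5})
    assert find_proxy("rs1", outcome, ld) is None


def test_proxy_target_missing_from_ld_raises():
    with pytest.raises(KeyError):
        find_proxy("rsX", make_set([]), _ld_with_r(["rs1"], [100], {}))


def test_negative_r_proxy_mapping_against_haplotype_oracle(rng):
    """A negatively correlated proxy must have its alleles swapped so the
    effective allele tracks the target's; verified on a simulated panel."""
    n = 20_000
    h1 = (rng.random(n) < 0.4).astype(int)
    # proxy carrier allele anti-correlated with the target's
    h2 = np.where(rng.random(n) < 0.95, 1 - h1, h1)
    panel = np.column_stack([h1, h2])
    ld = ld_from_haplotypes(panel, ["rs1", "rs2"], [100, 200])
    assert ld.r_between("rs1", "rs2") < -0.8

    # outcome effect of +0.3 per copy of the h1-ish allele; at rs2 the
    # "effect allele" labels the anti-correlated 1-allele, so its beta is
    # negative in the outcome study
    outcome = make_set([make_record("rs2", pos=200, ea="A", oa="G",
                                    beta=-0.3, eaf=float(1 - h1.mean()))])
    exposure = [make_record("rs1", pos=100, ea="A", oa="G", beta=0.5,
                            eaf=float(h1.mean()), pval=1e-20)]
    rows = harmonize_instrument(exposure, outcome, ld)
    assert rows[0].action == "proxied"
    # after mapping, the outcome beta aligns with the exposure effect allele
    assert rows[0].beta_y == pytest.approx(0.3)
    assert rows[0].beta_x == 0.5


def test_missing_snp_without_ld_reports_drop():
    rows = harmonize_instrument([make_record("rs1")], make_set([]), None)
    assert rows[0].action == "dropped"
    assert rows[0].drop_reason == "no_outcome_record"
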