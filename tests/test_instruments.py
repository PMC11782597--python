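"""Instrument selection against brute-force oracles, and strength formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protscreen import (
    LDMatrix,
    SelectionConfig,
    clump,
    compute_f_stat,
    compute_r2,
    select_cis_instrument,
)
from protscreen.sumstats import GeneAnnotation

from conftest import make_record, make_set

# hand-evaluated: R2 = 0.125 / (0.125 + 0.0001*2*35559*0.25) = 0.125/1.90295
R2_EXAMPLE = 0.125 / 1.90295


def test_r2_zero_effect():
    assert compute_r2(0.0, 0.5, 0.01, 35559) == 0.0


def test_r2_hand_example():
    got = compute_r2(0.5, 0.5, 0.01, 35559)
    assert got == pytest.approx(R2_EXAMPLE, abs=1e-10)
    assert got == pytest.approx(0.0657, abs=5e-5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    b=st.floats(0.01, 2.0),
    db=st.floats(0.01, 1.0),
    eaf=st.floats(0.05, 0.95),
    se=st.floats(1e-4, 0.5),
    n=st.integers(100, 100_000),
)
def test_r2_monotone_in_effect_size(b, db, eaf, se, n):
    assert compute_r2(b + db, eaf, se, n) > compute_r2(b, eaf, se, n)
    assert 0 <= compute_r2(b, eaf, se, n) < 1


def test_f_stat_hand_examples():
    assert compute_f_stat(0.0, 1000) == 0.0
    assert compute_f_stat(0.5, 102, 1) == pytest.approx(100.0, abs=1e-10)
    assert compute_f_stat(0.0657, 35559, 1) == pytest.approx(
        0.0657 * 35557 / 0.9343, abs=1e-10)
    # the screen's strength criterion at deCODE-like magnitudes
    assert compute_f_stat(0.0657, 35559, 1) > 10


def test_f_stat_domain_errors():
    with pytest.raises(ValueError):
        compute_f_stat(0.5, 2, 1)
    with pytest.raises(ValueError):
        compute_f_stat(1.0, 100, 1)


# --- cis instrument selection ---


def _ld(rsids, positions, r2_pairs=None, m=None):
    m = m or len(rsids)
    r = np.eye(m)
    for (i, j), v in (r2_pairs or {}).items():
        r[i, j] = r[j, i] = np.sqrt(v)
    return LDMatrix(list(rsids), r, list(positions))


GENE = GeneAnnotation("GENE", "1", 5_000_000)


def test_no_candidate_returns_none():
    sset = make_set([make_record("rs1", pos=5_000_000, pval=1e-6)])
    assert select_cis_instrument(sset, GENE, None) is None


def test_single_candidate_is_sentinel():
    sset = make_set([
        make_record("rs1", pos=5_000_000, pval=1e-12),
        make_record("rs2", pos=5_001_000, pval=1e-6),   # above threshold
        make_record("rs3", pos=9_000_000, pval=1e-20),  # outside cis window
    ])
    instr = select_cis_instrument(sset, GENE, None)
    assert instr.sentinel.rsid == "rs1"
    assert instr.is_cis and instr.n_snp == 1


def test_cis_window_is_closed_interval():
    cfg = SelectionConfig()
    sset = make_set([make_record("rs1", pos=GENE.tss + 1_000_000, pval=1e-12)])
    assert select_cis_instrument(sset, GENE, None, cfg) is not None
    sset = make_set([make_record("rs1", pos=GENE.tss + 1_000_001, pval=1e-12)])
    assert select_cis_instrument(sset, GENE, None, cfg) is None


def test_three_candidate_merge_example():
    # two SNPs in high LD plus a third, independent but with overlapping
    # flanks: all merge into one region; sentinel is the global lowest p
    recs = [
        make_record("rs1", pos=4_900_000, pval=1e-30),
        make_record("rs2", pos=4_905_000, pval=1e-25),
        make_record("rs3", pos=5_200_000, pval=1e-12),
    ]
    ld = _ld(["rs1", "rs2", "rs3"], [4_900_000, 4_905_000, 5_200_000],
             {(0, 1): 0.95})
    instr = select_cis_instrument(make_set(recs), GENE, ld)
    assert instr.sentinel.rsid == "rs1"
    assert oracle_sentinel(recs, ld, SelectionConfig()) == "rs1"


def oracle_sentinel(recs, ld, cfg):
    """Exhaustive region merging: iterate to a fixpoint, then pick the
    lowest-p member of the region holding the overall lowest-p SNP."""
    regions = [
        {"members": [r], "lo": r.variant.pos - cfg.region_flank_bp,
         "hi": r.variant.pos + cfg.region_flank_bp}
        for r in recs
    ]

    def touches(a, b):
        if not (a["hi"] < b["lo"] or a["lo"] > b["hi"]):
            return True
        for x in a["members"]:
            for y in b["members"]:
                r2 = ld.r2_between(x.rsid, y.rsid) if ld else None
                if r2 is not None and r2 >= cfg.merge_r2:
                    return True
        return False

    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if touches(regions[i], regions[j]):
                    regions[i]["members"] += regions[j]["members"]
                    regions[i]["lo"] = min(regions[i]["lo"], regions[j]["lo"])
                    regions[i]["hi"] = max(regions[i]["hi"], regions[j]["hi"])
                    del regions[j]
                    changed = True
                    break
            if changed:
                break
    top = min(recs, key=lambda r: (r.pval, r.variant.pos, r.rsid))
    home = next(reg for reg in regions if top in reg["members"])
    return min(home["members"], key=lambda r: (r.pval, r.variant.pos, r.rsid)).rsid


@pytest.mark.parametrize("seed", range(8))
def test_selection_matches_merge_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 11))
    positions = sorted(rng.choice(np.arange(4_000_000, 6_000_000, 1000),
                                  size=m, replace=False).tolist())
    recs = [
        make_record(f"rs{i}", pos=int(positions[i]),
                    pval=float(10 ** rng.uniform(-30, -9.8)))
        for i in range(m)
    ]
    r = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r[i, j] = r[j, i] = rng.uniform(0, 1)
    ld = LDMatrix([f"rs{i}" for i in range(m)], (r + r.T) / 2, positions)
    cfg = SelectionConfig()
    instr = select_cis_instrument(make_set(recs), GENE, ld, cfg)
    assert instr.sentinel.rsid == oracle_sentinel(recs, ld, cfg)


def test_sentinel_tie_breaks_to_lower_position():
    recs = [
        make_record("rsB", pos=5_001_000, pval=1e-12),
        make_record("rsA", pos=5_000_000, pval=1e-12),
    ]
    instr = select_cis_instrument(make_set(recs), GENE, None)
    assert instr.sentinel.rsid == "rsA"


# --- clumping ---


def oracle_clump(recs, ld, cfg, thresh):
    pool = sorted([r for r in recs if r.pval < thresh],
                  key=lambda r: (r.pval, r.variant.pos, r.rsid))
    kept = []
    while pool:
        idx = pool[0]
        kept.append(idx)
        nxt = []
        for r in pool[1:]:
            near = (r.variant.chrom == idx.variant.chrom
                    and abs(r.variant.pos - idx.variant.pos) <= cfg.clump_window_bp)
            r2 = ld.r2_between(idx.rsid, r.rsid) if ld else None
            if near and r2 is not None and r2 > cfg.clump_r2:
                continue
            nxt.append(r)
        pool = nxt
    return [r.rsid for r in kept]


def test_clump_empty_when_nothing_significant():
    sset = make_set([make_record("rs1", pval=1e-6)])
    assert clump(sset, None) == []


def test_clump_window_semantics():
    # r2 = 0.9 but 50 kb apart: outside the 10 kb window, both retained
    recs = [
        make_record("rs1", pos=1_000_000, pval=1e-10),
        make_record("rs2", pos=1_050_000, pval=1e-9),
    ]
    ld = _ld(["rs1", "rs2"], [1_000_000, 1_050_000], {(0, 1): 0.9})
    kept = clump(make_set(recs), ld)
    assert {r.rsid for r in kept} == {"rs1", "rs2"}


def test_clump_discards_correlated_neighbor():
    recs = [
        make_record("rs1", pos=1_000_000, pval=1e-10),
        make_record("rs2", pos=1_005_000, pval=1e-9),
    ]
    ld = _ld(["rs1", "rs2"], [1_000_000, 1_005_000], {(0, 1): 0.5})
    kept = clump(make_set(recs), ld)
    assert [r.rsid for r in kept] == ["rs1"]


@pytest.mark.parametrize("seed", range(6))
def test_clump_matches_greedy_oracle_on_ar1_ld(seed):
    from protscreen import simulate_ld_panel

    rng = np.random.default_rng(seed)
    m = 20
    positions = [1_000_000 + 4000 * j for j in range(m)]
    _, _, ld = simulate_ld_panel(m, 0.8, seed=seed, positions=positions)
    recs = [
        make_record(ld.rsids[j], pos=positions[j],
                    pval=float(10 ** rng.uniform(-15, -2)))
        for j in range(m)
    ]
    cfg = SelectionConfig()
    got = [r.rsid for r in clump(make_set(recs), ld, cfg)]
    assert got == oracle_clump(recs, ld, cfg, cfg.pthreshold_outcome)


def test_clump_invariant_to_input_order(rng):
    recs = [
        make_record(f"rs{i}", pos=1_000_000 + 3000 * i,
                    pval=float(10 ** rng.uniform(-15, -7)))
        for i in range(10)
    ]
    ld = _ld([f"rs{i}" for i in range(10)],
             [1_000_000 + 3000 * i for i in range(10)],
             {(i, i + 1): 0.3 for i in range(9)})
    ref = [r.rsid for r in clump(make_set(recs), ld)]
    for _ in range(3):
        rng.shuffle(recs)
        assert [r.rsid for r in clump(make_set(recs), ld)] == ref
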