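"""LD computation, clumping and proxy search against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postgwas import allele_freq, best_proxy, greedy_clump, pairwise_r2
from postgwas.errors import MonomorphicSnpError, SnpLookupError, ValidationError
from postgwas.simulate import generate_panel

from conftest import correlated_column, make_panel


# ------------------------------------------------------------- allele_freq

@pytest.mark.parametrize(
    "column, expected",
    [([0, 0, 0, 0], 0.0), ([1, 1, 1, 1], 1.0), ([0, 1, 0, 1], 0.5)],
)
def test_allele_freq_is_column_mean(column, expected):
    panel = make_panel({"a": column})
    assert allele_freq(panel, "a") == expected


def test_allele_freq_unknown_snp_raises():
    panel = make_panel({"a": [0, 1]})
    with pytest.raises(SnpLookupError):
        allele_freq(panel, "nope")


# ------------------------------------------------------------- pairwise_r2

def test_r2_perfect_ld_identical_and_flipped():
    a = np.array([0, 1, 0, 1, 1, 0])
    panel = make_panel({"a": a, "b": a, "c": 1 - a})
    assert pairwise_r2(panel, "a", "b") == pytest.approx(1.0)
    assert pairwise_r2(panel, "a", "c") == pytest.approx(1.0)  # r = -1


def test_r2_independent_haplotypes_zero():
    panel = make_panel({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
    assert pairwise_r2(panel, "a", "b") == pytest.approx(0.0)


def test_r2_from_haplotype_counts():
    # counts AB=3, Ab=1, aB=1, ab=3 over 8 haplotypes:
    # p_ab = 3/8, p_a = p_b = 1/2 -> (0.375 - 0.25)^2 / (0.25 * 0.25) = 0.25
    a = [1, 1, 1, 1, 0, 0, 0, 0]
    b = [1, 1, 1, 0, 1, 0, 0, 0]
    panel = make_panel({"a": a, "b": b})
    assert pairwise_r2(panel, "a", "b") == pytest.approx(0.25)


def test_r2_monomorphic_is_error_not_zero():
    panel = make_panel({"a": [0, 0, 0], "b": [0, 1, 0]})
    with pytest.raises(MonomorphicSnpError):
        pairwise_r2(panel, "a", "b")


@settings(derandomize=True, max_examples=200)
@given(st.data())
def test_r2_matches_corrcoef_oracle_and_is_symmetric(data):
    """Haplotype-frequency r^2 equals the squared Pearson correlation of the
    two indicator columns (computed independently via numpy.corrcoef)."""
    n = data.draw(st.integers(4, 20))
    a = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    b = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if a.min() == a.max() or b.min() == b.max():
        return  # monomorphic draws are covered by the error test
    panel = make_panel({"a": a, "b": b})
    r2 = pairwise_r2(panel, "a", "b")
    assert r2 == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12)
    assert r2 == pytest.approx(pairwise_r2(panel, "b", "a"))
    assert -1e-12 <= r2 <= 1 + 1e-12


# ------------------------------------------------------------ greedy_clump

def _reference_clump(variants, panel, r2_threshold, window_bp):
    """Independent clumping oracle: r^2 via numpy.corrcoef, explicit loop."""
    R2 = np.corrcoef(panel.H.T.astype(float)) ** 2
    idx = {s: i for i, s in enumerate(panel.snp_ids)}
    key = lambda t: (t[1], str(panel.chrom[idx[t[0]]]), int(panel.pos[idx[t[0]]]), t[0])
    todo = sorted(variants, key=key)
    out = []
    while todo:
        snp, p = todo[0]
        i = idx[snp]
        members = [snp] + [
            s for s, _ in todo[1:]
            if str(panel.chrom[idx[s]]) == str(panel.chrom[i])
            and (window_bp is None or abs(int(panel.pos[idx[s]]) - int(panel.pos[i])) <= window_bp)
            and R2[i, idx[s]] > r2_threshold
        ]
        out.append((snp, tuple(sorted(members))))
        todo = [t for t in todo if t[0] not in members]
    return out


def test_clump_single_variant():
    panel = make_panel({"a": [0, 1, 0, 1]})
    clumps = greedy_clump([("a", 1e-5)], panel, 0.05)
    assert len(clumps) == 1 and clumps[0].members == ["a"]


def test_clump_high_ld_pair_merges_under_lowest_p():
    rng = np.random.default_rng(7)
    a = (rng.random(400) < 0.5).astype(np.uint8)
    b = correlated_column(a, 0.9, rng)
    panel = make_panel({"a": a, "b": b})
    clumps = greedy_clump([("a", 1e-8), ("b", 1e-10)], panel, 0.05)
    assert len(clumps) == 1
    assert clumps[0].index_snp == "b"
    assert clumps[0].index_p <= 1e-10


def test_clump_below_threshold_stays_independent():
    # haplotype counts AB=6, Ab=4, aB=4, ab=6 give r^2 = 0.04 exactly,
    # just below the 0.05 threshold -> two clumps
    a = np.array([1] * 10 + [0] * 10)
    b = np.array([1] * 6 + [0] * 4 + [1] * 4 + [0] * 6)
    panel = make_panel({"a": a, "b": b})
    assert pairwise_r2(panel, "a", "b") == pytest.approx(0.04)
    assert len(greedy_clump([("a", 1e-8), ("b", 1e-7)], panel, 0.05)) == 2


def test_clump_recovers_planted_blocks_and_matches_oracle():
    panel, truth = generate_panel(1000, 5, 4, within_block_r2=0.6, seed=3)
    variants = [(s, p) for s, p in zip(panel.snp_ids, np.linspace(1e-10, 1e-6, 20))]
    clumps = greedy_clump(variants, panel, 0.05)
    assert len(clumps) == 5
    got = {c.index_snp: tuple(sorted(c.members)) for c in clumps}
    for b in range(5):
        block = tuple(sorted(s for s, bb in truth.block_membership.items() if bb == b))
        assert block in got.values()
    ref = dict(_reference_clump(variants, panel, 0.05, 1_000_000))
    assert got == ref


@settings(derandomize=True, max_examples=150, deadline=None)
@given(st.data())
def test_clump_agrees_with_oracle_on_small_instances(data):
    """Greedy clumping equals the exhaustive reference on every <=8-variant
    instance drawn, including tied P-values and multi-chromosome layouts."""
    m = data.draw(st.integers(1, 8))
    n = data.draw(st.integers(6, 12))
    cols = []
    for _ in range(m):
        c = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if c.min() == c.max():
            c[0] ^= 1  # keep every column polymorphic
        cols.append(c)
    chrom = [str(data.draw(st.integers(1, 2))) for _ in range(m)]
    order = np.lexsort((np.zeros(m), [int(c) for c in chrom]))
    pos = np.zeros(m, dtype=int)
    last = {}
    for i in order:
        step = data.draw(st.sampled_from([500, 600_000]))
        pos[i] = last.get(chrom[i], 0) + step
        last[chrom[i]] = pos[i]
    panel = make_panel([cols[i] for i in order],
                       pos=[pos[i] for i in order],
                       chrom=[chrom[i] for i in order])
    pvals = data.draw(st.lists(st.sampled_from([1e-10, 1e-8, 1e-8, 0.01]),
                               min_size=m, max_size=m))
    variants = list(zip(panel.snp_ids, pvals))
    # thresholds chosen off the rationals tiny haplotype counts can hit
    # exactly, where strict ">" is float-representation knife-edge
    threshold = data.draw(st.sampled_from([0.0513, 0.2977, 0.7983]))
    window = data.draw(st.sampled_from([None, 1_000_000]))
    clumps = greedy_clump(variants, panel, threshold, window_bp=window)
    got = {c.index_snp: tuple(sorted(c.members)) for c in clumps}
    assert got == dict(_reference_clump(variants, panel, threshold, window))
    # partition invariant
    members = [s for c in clumps for s in c.members]
    assert sorted(members) == sorted(s for s, _ in variants)
    # index leads its clump on P
    pmap = dict(variants)
    for c in clumps:
        assert all(c.index_p <= pmap[s] for s in c.members)


def test_clump_count_monotone_in_threshold():
    panel, _ = generate_panel(600, 4, 4, within_block_r2=0.5, seed=11)
    variants = [(s, 1e-6) for s in panel.snp_ids]
    counts = [len(greedy_clump(variants, panel, t)) for t in (0.8, 0.4, 0.1, 0.02)]
    # clump count is non-increasing as the threshold decreases
    assert counts == sorted(counts, reverse=True)


def test_clump_missing_variant_policy():
    panel = make_panel({"a": [0, 1, 0, 1]})
    clumps = greedy_clump([("a", 1e-5), ("ghost", 1e-9)], panel, 0.05)
    assert [c.index_snp for c in clumps] == ["a"]
    with pytest.raises(SnpLookupError):
        greedy_clump([("ghost", 1e-9)], panel, 0.05, missing="error")
    with pytest.raises(ValidationError):
        greedy_clump([("a", 1e-5)], panel, r2_threshold=1.5)


# -------------------------------------------------------------- best_proxy

def test_best_proxy_target_itself_wins():
    panel = make_panel({"a": [0, 1, 0, 1], "b": [0, 1, 1, 1]})
    assert best_proxy("a", ["a", "b"], panel, 0.5) == ("a", pytest.approx(1.0))


def test_best_proxy_none_below_floor_or_empty():
    panel = make_panel({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
    assert best_proxy("a", ["b"], panel, 0.5) is None
    assert best_proxy("a", [], panel, 0.1) is None


def test_best_proxy_planted_at_075(rng):
    founder = (rng.random(2000) < 0.5).astype(np.uint8)
    proxy = correlated_column(founder, 0.75, rng)
    far = (rng.random(2000) < 0.5).astype(np.uint8)
    panel = make_panel({"t": founder, "p": proxy, "x": far})
    r2 = pairwise_r2(panel, "t", "p")
    assert r2 == pytest.approx(0.75, abs=0.05)
    assert best_proxy("t", ["p", "x"], panel, 0.7) == ("p", pytest.approx(r2))
    assert best_proxy("t", ["p", "x"], panel, max(0.8, r2 + 0.01)) is None
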