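"""Harmonization, inflation adjustment and replication assessment."""

import numpy as np
import pytest
from scipy import stats

from postgwas import assess, bonferroni_alpha, harmonize, intercept_adjust
from postgwas.errors import HarmonizationError, ValidationError
from postgwas.replication import adjust_p, round_sig
from postgwas.types import RiskVariant


def _v(rsid="rs1", ea="A", oa="G", or_=1.25, eaf=0.3, p=1e-8):
    return RiskVariant(rsid=rsid, chrom="1", pos=100, effect_allele=ea,
                       other_allele=oa, or_=or_, p=p, eaf=eaf)


# --------------------------------------------------------------- threshold

def test_bonferroni_values():
    assert round_sig(bonferroni_alpha(0.05, 31)) == 0.0016
    assert bonferroni_alpha(0.05, 1) == 0.05
    assert round_sig(bonferroni_alpha(0.05, 21_472_000)) == 2.3e-9
    with pytest.raises(ValidationError):
        bonferroni_alpha(0.05, 0)


# ------------------------------------------------------- intercept_adjust

def test_intercept_identity_and_arithmetic():
    chi2_adj, _ = intercept_adjust(10.73, 1.073)
    assert chi2_adj == pytest.approx(10.0)
    adj, p = intercept_adjust(5.0, 1.0)
    assert adj == 5.0 and p == pytest.approx(stats.chi2.sf(5.0, 1))
    with pytest.raises(ValidationError):
        intercept_adjust(5.0, 0.0)


def test_adjust_p_roundtrip():
    # chi2(1e-8) = 32.841; /1.073 then re-evaluate the tail
    assert adjust_p(1e-8, 1.073) == pytest.approx(3.16e-8, rel=5e-3)
    assert adjust_p(0.01, 1.073) > 0.01  # intercept > 1 weakens evidence


# -------------------------------------------------------------- harmonize

def test_harmonize_truth_table():
    """All eight allele configurations of a non-palindromic A/G variant
    resolve to the original orientation or raise."""
    orig = _v(ea="A", oa="G", or_=1.25, eaf=0.3)
    same = [("A", "G"), ("T", "C")]        # identity / pure strand flip
    swapped = [("G", "A"), ("C", "T")]     # swap / strand flip + swap
    for ea, oa in same:
        h = harmonize(orig, _v(ea=ea, oa=oa, or_=1.25, eaf=0.3))
        assert h.or_ == pytest.approx(1.25) and h.eaf == pytest.approx(0.3)
        assert (h.effect_allele, h.other_allele) == ("A", "G")
    for ea, oa in swapped:
        h = harmonize(orig, _v(ea=ea, oa=oa, or_=1.25, eaf=0.3))
        assert h.or_ == pytest.approx(0.8)
        assert h.eaf == pytest.approx(0.7)
        assert h.effect_allele == "A"
    for ea, oa in [("A", "C"), ("C", "G"), ("T", "G"), ("G", "T")]:
        with pytest.raises(HarmonizationError):
            harmonize(orig, _v(ea=ea, oa=oa))


def test_harmonize_single_allele_records_read_same_strand():
    # only effect alleles recorded: equal letters -> identity, different -> swap
    orig = _v(ea="T", oa=None)
    assert harmonize(orig, _v(ea="T", oa=None, or_=1.1)).or_ == pytest.approx(1.1)
    h = harmonize(orig, _v(ea="A", oa=None, or_=1.12))  # palindromic letters
    assert h.or_ == pytest.approx(1 / 1.12)


def test_harmonize_swap_is_involution():
    orig = _v(ea="A", oa="G")
    rep = _v(ea="G", oa="A", or_=1.6, eaf=0.8)
    once = harmonize(orig, rep)
    twice = harmonize(orig, once)
    assert twice.or_ == pytest.approx(once.or_)
    assert twice.eaf == pytest.approx(once.eaf)
    # and swapping the swapped record against itself returns the start
    back = harmonize(rep, once)
    assert back.or_ == pytest.approx(rep.or_)


def test_harmonize_palindromic_freq_policy():
    orig = _v(ea="A", oa="T", eaf=0.2)
    rep = _v(ea="A", oa="T", or_=1.3, eaf=0.75)
    h = harmonize(orig, rep, palindromic_policy="freq")  # frequencies disagree -> swap
    assert h.or_ == pytest.approx(1 / 1.3)
    with pytest.raises(HarmonizationError):
        harmonize(orig, _v(ea="A", oa="T", eaf=0.45), palindromic_policy="freq")


# ----------------------------------------------------------------- assess

def test_assess_reproduces_reported_replication(fx):
    """28 of the 31 reported variants replicate at 0.05/31 with a 1.073
    inflation intercept; the failures are the CRB1, PDE4D and CDHR3 loci."""
    verdicts, summary = assess(
        fx.originals, fx.replication, alpha=0.05, intercept=1.073,
        proxy_map=fx.proxy_map,
    )
    assert summary["n_tested"] == 31
    assert summary["n_significant"] == 28
    assert round(summary["pct_significant"]) == 90
    failed = {v.rsid for v in verdicts if not v.significant}
    contexts = {fx.locus_context[r] for r in failed}
    assert contexts == {"[CRB1]", "[PDE4D]", "[CDHR3]"}
    # the proxy path was exercised for the one indel variant
    proxy_verdict = next(v for v in verdicts if v.rsid == "rs200634877")
    assert proxy_verdict.proxy_used == "rs166079"
    assert proxy_verdict.significant


def test_assess_perfect_and_inverted_replication():
    originals = [_v(rsid=f"rs{i}", or_=1.2) for i in range(5)]
    perfect = [_v(rsid=f"rs{i}", or_=1.2, p=1e-300) for i in range(5)]
    _, summary = assess(originals, perfect)
    assert summary["n_significant"] == 5
    inverted = [_v(rsid=f"rs{i}", or_=0.8, p=1e-300) for i in range(5)]
    _, summary = assess(originals, inverted)
    assert summary["n_direction_consistent"] == 0
    assert summary["n_significant"] == 0


def test_assess_untestable_and_verdict_invariants():
    originals = [_v(rsid="rs1"), _v(rsid="rs_missing")]
    replication = [_v(rsid="rs1", p=1e-20)]
    verdicts, summary = assess(originals, replication)
    assert len(verdicts) == len(originals)
    assert summary["n_tested"] == 1
    missing = next(v for v in verdicts if v.rsid == "rs_missing")
    assert not missing.testable and not missing.significant
    for v in verdicts:
        if v.significant:
            assert v.direction_consistent and v.p_adjusted < summary["threshold"]


def test_assess_null_calibration():
    """Under the null (uniform replication P, random directions), the
    Bonferroni threshold is calibrated: across many 31-variant replicates
    the count below alpha/31 matches its binomial expectation, and
    direction consistency is a coin flip."""
    rng = np.random.default_rng(5)
    m, reps, alpha = 31, 400, 0.05
    n_below = n_dir = 0
    thr = bonferroni_alpha(alpha, m)
    for _ in range(reps):
        originals = [
            _v(rsid=f"rs{i}", or_=float(rng.choice([0.9, 1.1]))) for i in range(m)
        ]
        replication = [
            _v(rsid=f"rs{i}", or_=float(np.exp(rng.normal(0, 0.05))),
               p=float(rng.uniform())) for i in range(m)
        ]
        verdicts, summary = assess(originals, replication, alpha=alpha)
        n_below += sum(v.p_adjusted < thr for v in verdicts)
        n_dir += summary["n_direction_consistent"]
    total = m * reps
    expect = total * thr
    assert abs(n_below - expect) <= 3 * np.sqrt(expect)
    assert abs(n_dir / total - 0.5) <= 3 * np.sqrt(0.25 / total)
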