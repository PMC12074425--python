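"""Phase maps, digitization/XOR, correlation refinement, and voting."""

import numpy as np
import pytest

from seizelect.cwc import CWCSeries
from seizelect.data_io import SeizureAnnotation
from seizelect.montage import N_CHANNELS
from seizelect.preprocess import BAND_NAMES, BandDecomposition
from seizelect.selection import (ChannelPair, EmptyPhaseError, PhaseInterval,
                                 PhaseMap, SCTMap, SelectionError, ICTAL,
                                 NO_SEIZURE, average_records, digitize,
                                 majority_vote, mean_abs_pcc, merge_bands,
                                 phase_intervals, phase_mean_cwc, select_pair,
                                 xor_candidates)


def _series(matrix):
    return CWCSeries(matrix=np.asarray(matrix, dtype=float), band="alpha")


def _decomp(sig: np.ndarray, fs: float = 256.0) -> BandDecomposition:
    """All five bands carry the same matrix; correlation tests control content."""
    return BandDecomposition("r", fs, {b: sig for b in BAND_NAMES})


# -- phase intervals --------------------------------------------------------

def test_guard_intervals_exclude_pre_and_post():
    anns = [SeizureAnnotation("r", 1000.0, 1040.0)]
    ivs = phase_intervals(3600.0, anns, guard_pre_s=600.0, guard_post_s=600.0)
    ns = sorted((iv.start_s, iv.end_s) for iv in ivs if iv.phase == NO_SEIZURE)
    assert ns == [(0.0, 400.0), (1640.0, 3600.0)]
    ictal = [(iv.start_s, iv.end_s) for iv in ivs if iv.phase == ICTAL]
    assert ictal == [(1000.0, 1040.0)]


def test_seizure_free_record_is_all_no_seizure():
    ivs = phase_intervals(100.0, [])
    assert [(iv.phase, iv.start_s, iv.end_s) for iv in ivs] == [(NO_SEIZURE, 0.0, 100.0)]


# -- phase means ------------------------------------------------------------

def test_phase_mean_over_full_series_is_column_mean(rng):
    m = rng.random((30, N_CHANNELS))
    got = phase_mean_cwc(_series(m), [PhaseInterval(ICTAL, 0.0, 30.0)], ICTAL)
    np.testing.assert_allclose(got, m.mean(axis=0))


def test_phase_mean_over_disjoint_intervals(rng):
    m = rng.random((60, N_CHANNELS))
    ivs = [PhaseInterval(NO_SEIZURE, 0.0, 10.0), PhaseInterval(NO_SEIZURE, 20.0, 50.0)]
    got = phase_mean_cwc(_series(m), ivs, NO_SEIZURE)
    expected = np.concatenate([m[0:10], m[20:50]]).mean(axis=0)
    np.testing.assert_allclose(got, expected)


def test_phase_mean_skips_nan_rows_and_partial_windows(rng):
    m = rng.random((10, N_CHANNELS))
    m[3] = np.nan
    got = phase_mean_cwc(_series(m), [PhaseInterval(ICTAL, 0.0, 10.0)], ICTAL)
    np.testing.assert_allclose(got, np.delete(m, 3, axis=0).mean(axis=0))
    with pytest.raises(EmptyPhaseError):
        phase_mean_cwc(_series(m), [PhaseInterval(ICTAL, 5.2, 5.9)], ICTAL)


# -- band merging and record averaging --------------------------------------

def test_merge_bands_minmax_then_average():
    v = np.arange(N_CHANNELS, dtype=float)
    per_band = {b: v for b in BAND_NAMES}
    per_band["delta"] = np.array([2.0, 4.0, 6.0] + [6.0] * (N_CHANNELS - 3))
    got = merge_bands(per_band)
    # delta contributes (0, 0.5, 1, 1, ...), the others the identity ramp
    ramp = v / v.max()
    expected = (np.concatenate([[0.0, 0.5], np.ones(N_CHANNELS - 2)]) + 4 * ramp) / 5
    np.testing.assert_allclose(got, expected)


def test_merge_bands_opposing_bands_average_to_half():
    a = np.zeros(N_CHANNELS); a[0] = 1.0
    b = np.ones(N_CHANNELS); b[0] = 0.0
    per_band = {name: (a if i % 2 else b) for i, name in enumerate(BAND_NAMES)}
    got = merge_bands(per_band)
    assert got[0] == pytest.approx(2 / 5)  # a chosen for 2 of 5 bands


def test_merge_bands_constant_band_contributes_half():
    per_band = {b: np.arange(N_CHANNELS, dtype=float) for b in BAND_NAMES}
    per_band["gamma"] = np.full(N_CHANNELS, 7.0)
    got = merge_bands(per_band)
    ramp = np.arange(N_CHANNELS) / (N_CHANNELS - 1)
    np.testing.assert_allclose(got, (4 * ramp + 0.5) / 5)


def test_average_records_rescales_and_rejects_degenerate(rng):
    m1 = rng.random(N_CHANNELS)
    single = average_records([m1])
    assert single.values.min() == 0.0 and single.values.max() == 1.0
    with pytest.raises(SelectionError):
        average_records([np.full(N_CHANNELS, 0.3)])
    with pytest.raises(SelectionError):
        average_records([])


# -- digitization and XOR ---------------------------------------------------

def test_digitize_is_strict_at_threshold():
    bits = digitize(np.array([1.0, 0.95, 0.9, 0.2]), 0.9)
    np.testing.assert_array_equal(bits, [True, True, False, False])


def test_rescaled_map_always_sets_at_least_one_bit(rng):
    pm = average_records([rng.random(N_CHANNELS)])
    assert digitize(pm.values).sum() >= 1


@pytest.mark.parametrize("ns_set,ic_set,expected_a,expected_b", [
    ({19}, {9}, {19}, {9}),
    ({9, 19}, {9}, {19}, set()),   # channel 9 dominant in both: excluded
    ({5, 7}, {5, 7}, set(), set()),
])
def test_xor_candidates(ns_set, ic_set, expected_a, expected_b):
    bits_ns = np.zeros(N_CHANNELS, dtype=bool)
    bits_ic = np.zeros(N_CHANNELS, dtype=bool)
    bits_ns[[i - 1 for i in ns_set]] = True
    bits_ic[[i - 1 for i in ic_set]] = True
    a, b = xor_candidates(SCTMap(bits_ictal=bits_ic, bits_no_seizure=bits_ns))
    assert a == expected_a and b == expected_b


# -- correlation ------------------------------------------------------------

def test_mean_abs_pcc_identical_and_negated(rng):
    sig = np.zeros((N_CHANNELS, 256 * 5))
    x = rng.standard_normal(256 * 5)
    sig[0], sig[1], sig[2] = x, x.copy(), -x
    dec = _decomp(sig)
    assert mean_abs_pcc(dec, 1, 2) == pytest.approx(1.0)
    assert mean_abs_pcc(dec, 1, 3) == pytest.approx(1.0)


def test_mean_abs_pcc_independent_noise_is_small(rng):
    sig = rng.standard_normal((N_CHANNELS, 256 * 60))
    # |r| of independent n=256 samples has mean ~ sqrt(2/(pi*256)) ~ 0.05
    assert mean_abs_pcc(_decomp(sig), 1, 2) < 0.15


def test_mean_abs_pcc_symmetric_and_affine_invariant(rng):
    sig = rng.standard_normal((N_CHANNELS, 256 * 10))
    dec = _decomp(sig)
    r12 = mean_abs_pcc(dec, 1, 2)
    assert mean_abs_pcc(dec, 2, 1) == pytest.approx(r12)
    scaled = sig.copy()
    scaled[0] = 5.0 * scaled[0] - 3.0
    assert mean_abs_pcc(_decomp(scaled), 1, 2) == pytest.approx(r12)
    with pytest.raises(ValueError):
        mean_abs_pcc(dec, 3, 3)


# -- pair selection ---------------------------------------------------------

def _correlated_decomp(rng, rho_pairs):
    """Channels built so that requested pairs have controlled correlation."""
    n = 256 * 20
    base = rng.standard_normal((N_CHANNELS, n))
    sig = base.copy()
    for (i, j), rho in rho_pairs.items():
        sig[j - 1] = rho * base[i - 1] + np.sqrt(1 - rho**2) * base[j - 1]
    return _decomp(sig)


def test_select_pair_minimizes_rho(rng):
    """A={19,21}, B={9}: the less correlated of the two pairs wins."""
    dec = _correlated_decomp(rng, {(9, 21): 0.8})
    pair = select_pair({19, 21}, {9}, dec)
    assert (pair.channel_a, pair.channel_b) == (19, 9)
    assert pair.rho_bar < mean_abs_pcc(dec, 21, 9)


def test_select_pair_single_candidates(rng):
    dec = _correlated_decomp(rng, {})
    pair = select_pair({19}, {9}, dec)
    assert (pair.channel_a, pair.channel_b) == (19, 9)
    assert 0.0 <= pair.rho_bar <= 1.0


def test_select_pair_fallback_single_phase(rng):
    """Both candidates from one phase (ictal): least-correlated pair within
    the set, ordered by channel number."""
    dec = _correlated_decomp(rng, {(9, 15): 0.9, (9, 11): 0.1})
    pair = select_pair(set(), {9, 11, 15}, dec)
    assert (pair.channel_a, pair.channel_b) == (9, 11)


def test_select_pair_fallback_threshold_lowering(rng):
    """Empty XOR on both sides: the threshold drops until candidates exist."""
    dec = _correlated_decomp(rng, {})
    values_ic = np.full(N_CHANNELS, 0.1); values_ic[8] = 1.0
    values_ns = np.full(N_CHANNELS, 0.1); values_ns[18] = 1.0
    # both maps share their argmax bits only -> simulate both-empty by
    # passing identical bit sets upstream
    maps = {ICTAL: PhaseMap(ICTAL, values_ic, 1), NO_SEIZURE: PhaseMap(NO_SEIZURE, values_ns, 1)}
    pair = select_pair(set(), set(), dec, phase_maps=maps, threshold=0.9)
    assert {pair.channel_a, pair.channel_b} == {19, 9}


def test_select_pair_failure(rng):
    dec = _correlated_decomp(rng, {})
    with pytest.raises(SelectionError):
        select_pair(set(), {9}, dec)


# -- per-record stats --------------------------------------------------------

def test_seizure_free_records_excluded_by_default(rng):
    """Seizure-free records carry no phase vectors unless opted in."""
    from conftest import make_record
    from seizelect.selection import record_phase_stats

    rec = make_record(rng.normal(0, 20, (N_CHANNELS, 256 * 30)))
    stats = record_phase_stats(rec, [], guard_s=5.0)
    assert stats.per_band_ictal is None and stats.per_band_no_seizure is None
    opted = record_phase_stats(rec, [], guard_s=5.0, include_seizure_free=True)
    assert opted.per_band_ictal is None
    assert set(opted.per_band_no_seizure) == set(BAND_NAMES)


# -- voting -----------------------------------------------------------------

def test_majority_vote_frequency_and_ties():
    p = lambda a, b, r: ChannelPair(a, b, r)
    assert majority_vote([p(19, 9, .3)] * 3)  == ChannelPair(19, 9)
    winner = majority_vote([p(19, 9, .3), p(19, 9, .3), p(13, 15, .1)])
    assert (winner.channel_a, winner.channel_b) == (19, 9)
    # 2-2 tie: lower mean rho wins
    winner = majority_vote([p(19, 9, .4), p(19, 9, .4), p(13, 15, .1), p(13, 15, .1)])
    assert (winner.channel_a, winner.channel_b) == (13, 15)
    with pytest.raises(SelectionError):
        majority_vote([])
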