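"""EMTF curve construction, feature extraction and group statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from earevol import synth
from earevol.transfer import (EMTFCurve, FrequencyResponse, average_frames,
                              combine_emtf, compare_groups, concat_segments,
                              default_grid_khz, extract_features,
                              group_mean, metf_db)


def curve(mag, specimen="s", species="X"):
    g = default_grid_khz()
    return EMTFCurve(specimen, species, g, np.broadcast_to(
        np.asarray(mag, float), g.shape).copy())


# ---------------------------------------------------------------- frames

def test_average_of_identical_frames_is_that_frame():
    z = np.array([1 + 1j, 2 - 1j, 0.5j])
    fr = FrequencyResponse("s", "X", [100, 200, 300], np.tile(z, (4, 1)))
    assert np.allclose(average_frames(fr), z)


def test_average_of_conjugate_pair_is_real_part():
    z = np.array([1 + 2j, -3 + 0.5j])
    frames = np.vstack([z, np.conj(z)])
    assert np.allclose(average_frames(frames), z.real)


def test_empty_frames_rejected():
    with pytest.raises(ValueError):
        average_frames(np.zeros((0,), dtype=complex).reshape(1, 0))


# -------------------------------------------------------------- segments

def test_single_segment_identity():
    f = np.array([100.0, 150, 200])
    z = np.array([1 + 1j, 2.0, 3 - 1j])
    uf, uz = concat_segments([(f, z)])
    assert np.allclose(uf, f) and np.allclose(uz, z)


def test_identical_overlap_unchanged():
    f1 = np.array([100.0, 150, 200])
    f2 = np.array([150.0, 200, 250])
    z1 = np.array([1.0, 2.0, 3.0], dtype=complex)
    z2 = np.array([2.0, 3.0, 4.0], dtype=complex)
    uf, uz = concat_segments([(f1, z1), (f2, z2)])
    assert np.allclose(uf, [100, 150, 200, 250])
    assert np.allclose(uz, [1, 2, 3, 4])


def test_overlap_merges_in_log_magnitude():
    """Two flat segments 2 dB apart merge to 1 dB from each."""
    f1 = np.array([100.0, 150, 200])
    f2 = np.array([150.0, 200, 250])
    lo = np.full(3, 1.0, dtype=complex)
    hi = np.full(3, 10 ** (2 / 20), dtype=complex)
    _, uz = concat_segments([(f1, lo), (f2, hi)])
    merged_db = 20 * np.log10(np.abs(uz[1]))   # at 150 Hz
    assert merged_db == pytest.approx(1.0, abs=0.01)


def test_gap_between_segments_rejected():
    with pytest.raises(ValueError):
        concat_segments([(np.array([100.0, 150]), np.ones(2, complex)),
                         (np.array([300.0, 350]), np.ones(2, complex))])


# --------------------------------------------------------------- metf_db

def test_reference_magnitude_is_zero_db():
    f = np.array([100.0, 1000, 10000])
    db = metf_db(f, np.ones(3, complex), default_grid_khz())
    assert np.allclose(db, 0.0, atol=1e-12)


def test_scaling_adds_constant_db(rng):
    f = np.geomspace(100, 10000, 40)
    z = rng.normal(size=40) + 1j * rng.normal(size=40)
    z += 3.0  # keep away from zero magnitude
    base = metf_db(f, z, default_grid_khz())
    scaled = metf_db(f, 10.0 * z, default_grid_khz())
    assert np.allclose(scaled - base, 20.0, atol=1e-10)


def test_resampling_on_grid_is_identity():
    g = default_grid_khz()
    mag = np.linspace(-30, 0, g.size)
    db = metf_db(g * 1e3, 10 ** (mag / 20) + 0j, g)
    assert np.allclose(db, mag, atol=1e-9)


def test_grid_outside_span_rejected():
    with pytest.raises(ValueError):
        metf_db(np.array([300.0, 5000.0]), np.ones(2, complex),
                default_grid_khz())


# ----------------------------------------------------------- combine/mean

def test_combine_is_pointwise_sum_and_commutes():
    a = curve(-20.0)
    b = curve(12.0)
    ab = combine_emtf(a, b)
    assert np.allclose(ab.magnitude_db, -8.0)
    assert np.allclose(ab.magnitude_db, combine_emtf(b, a).magnitude_db,
                       atol=1e-12)
    zero = curve(0.0)
    assert np.allclose(combine_emtf(a, zero).magnitude_db, a.magnitude_db)


def test_group_mean_is_db_mean():
    m = group_mean([curve(0.0), curve(10.0)])
    assert np.allclose(m.magnitude_db, 5.0)


# --------------------------------------------------------------- features

def single_peak_curve(center_khz=2.0):
    g = default_grid_khz()
    mag = -20.0 + 15.0 * np.exp(-np.log2(g / center_khz) ** 2 / 0.5)
    return EMTFCurve("s", "X", g, mag)


def test_single_peak_detected_at_construction_frequency():
    fs = extract_features(single_peak_curve(2.0))
    maxima = [(f, m) for k, f, m in fs.extrema if k == "max"]
    assert len(maxima) == 1
    assert maxima[0][0] == pytest.approx(2.0, rel=0.03)


def test_two_peak_one_notch_alternation():
    g = default_grid_khz()
    mag = (-20.0 + 12 * np.exp(-np.log2(g / 1.0) ** 2 / 0.18)
           + 12 * np.exp(-np.log2(g / 4.0) ** 2 / 0.18))
    fs = extract_features(EMTFCurve("s", "X", g, mag))
    kinds = [k for k, _, _ in fs.extrema]
    assert kinds == ["max", "min", "max"]
    assert len(fs.slopes) == 2
    assert fs.slopes[0] < 0 < fs.slopes[1]


def test_features_shift_with_constant_offset():
    c = single_peak_curve()
    f1 = extract_features(c)
    f2 = extract_features(EMTFCurve("s", "X", c.grid_khz,
                                    c.magnitude_db + 7.0))
    for (k1, fr1, m1), (k2, fr2, m2) in zip(f1.extrema, f2.extrema):
        assert k1 == k2 and fr1 == fr2
        assert m2 - m1 == pytest.approx(7.0, abs=1e-9)


def test_flat_curve_has_no_maximum():
    with pytest.raises(ValueError):
        extract_features(curve(0.0))


# ------------------------------------------------------------- comparison

def noisy_group(rng, n, offset=0.0, sd=3.0):
    g = default_grid_khz()
    base = -20.0 + 10 * np.exp(-np.log2(g / 1.5) ** 2)
    return [EMTFCurve(f"s{i}", "X", g,
                      base + offset + sd * rng.standard_normal(g.size))
            for i in range(n)]


def test_identical_groups_not_significant(rng):
    a = noisy_group(rng, 5)
    comp = compare_groups(a, a)
    assert np.allclose(comp.diff, 0.0)
    assert not comp.significant.any()
    assert comp.bands == []


def test_pvalues_match_brute_force_oracle(rng):
    """Raw F/t/Welch p values and the BH adjustment agree with hand-coded
    formulas on random instances."""
    for _ in range(25):
        na, nb = rng.integers(3, 7), rng.integers(3, 7)
        A = rng.normal(0, 1, (na, 12))
        B = rng.normal(0.5, 1.7, (nb, 12))
        g = default_grid_khz()[:12]
        ca = [EMTFCurve(f"a{i}", "A", g, A[i]) for i in range(na)]
        cb = [EMTFCurve(f"b{i}", "B", g, B[i]) for i in range(nb)]
        comp = compare_groups(ca, cb)
        for j in range(12):
            va, vb = A[:, j].var(ddof=1), B[:, j].var(ddof=1)
            Fp = stats.f.cdf(va / vb, na - 1, nb - 1)
            p_var = 2 * min(Fp, 1 - Fp)
            assert comp.p_variance[j] == pytest.approx(p_var, abs=1e-10)
            ma, mb = A[:, j].mean(), B[:, j].mean()
            if p_var < 0.05:  # Welch
                se = np.sqrt(va / na + vb / nb)
                t = (ma - mb) / se
                df = se ** 4 / ((va / na) ** 2 / (na - 1) +
                                (vb / nb) ** 2 / (nb - 1))
            else:             # pooled
                sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
                t = (ma - mb) / np.sqrt(sp * (1 / na + 1 / nb))
                df = na + nb - 2
            p = 2 * stats.t.sf(abs(t), df)
            assert comp.p_mean[j] == pytest.approx(p, abs=1e-10)
        # BH step-up by hand
        m = 12
        order = np.argsort(comp.p_mean)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            j = order[rank - 1]
            prev = min(prev, comp.p_mean[j] * m / rank)
            adj[j] = prev
        assert np.allclose(comp.p_adjusted, adj, atol=1e-10)


def test_bh_adjustment_properties(rng):
    a = noisy_group(rng, 5)
    b = noisy_group(rng, 5, offset=4.0)
    comp = compare_groups(a, b)
    assert np.all(comp.p_adjusted >= comp.p_mean - 1e-15)
    assert np.all((comp.p_adjusted >= 0) & (comp.p_adjusted <= 1))
    order = np.argsort(comp.p_mean)
    assert np.all(np.diff(comp.p_adjusted[order]) >= -1e-15)


def test_offset_band_is_detected(rng):
    """A +10 dB offset over one octave is flagged with the right sign."""
    g = default_grid_khz()
    bump = 10.0 * ((g >= 1.0) & (g <= 2.0))
    a = [EMTFCurve(f"a{i}", "A", g, bump + 2.0 * rng.standard_normal(g.size))
         for i in range(5)]
    b = [EMTFCurve(f"b{i}", "B", g, 2.0 * rng.standard_normal(g.size))
         for i in range(5)]
    comp = compare_groups(a, b)
    in_band = (g >= 1.1) & (g <= 1.9)
    assert comp.significant[in_band].mean() > 0.8
    assert all(bnd["sign"] == 1 for bnd in comp.bands
               if 1.0 <= bnd["start_khz"] <= 2.0)
    assert comp.fraction_significant["a_higher"] > \
        comp.fraction_significant["b_higher"]


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_combine_associative_on_common_grid(seed):
    rng = np.random.default_rng(seed)
    g = default_grid_khz()
    a, b, c = (EMTFCurve("s", "X", g, rng.normal(size=g.size))
               for _ in range(3))
    left = combine_emtf(combine_emtf(a, b), c)
    right = combine_emtf(a, combine_emtf(b, c))
    assert np.allclose(left.magnitude_db, right.magnitude_db, atol=1e-12)
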