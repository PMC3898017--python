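import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from chipregulon import peaks as pk
from chipregulon.io import TagLibrary
from chipregulon.simulate import SimulationConfig, simulate_dataset

# ---------------------------------------------------------------------------
# coverage


def test_single_tag_window():
    track = pk.CoverageTrack.from_positions(np.array([500]), w=100, length=1000)
    assert track.count(500) == 1
    assert track.count(400) == 1
    assert track.count(601) == 0


def test_raw_counts_conserve_library_size(rng):
    positions = rng.integers(1, 5000, size=800)
    track = pk.CoverageTrack.from_positions(positions, w=50, length=5000)
    assert track.raw.sum() == 800
    assert track.tag_count == 800


def test_coverage_matches_naive_recount(rng):
    positions = np.sort(rng.integers(1, 10_000, size=1500))
    w = 100
    track = pk.CoverageTrack.from_positions(positions, w=w, length=10_000)
    for x in rng.integers(1, 10_000, size=1000):
        naive = int(np.sum((positions >= x - w) & (positions <= x + w)))
        assert track.count(int(x)) == naive


def test_coverage_w_nonpositive_errors():
    with pytest.raises(ValueError):
        pk.CoverageTrack.from_positions(np.array([5]), w=0, length=10)


# ---------------------------------------------------------------------------
# candidate peaks


def _track(positions, w=100, length=10_000, strand="+"):
    return pk.CoverageTrack.from_positions(
        np.asarray(positions), w=w, length=length, strand=strand
    )


def test_zscore_worked_example():
    # a=100, b=10 -> z = 89/sqrt(110)
    assert pk._zscore(100, 10) == pytest.approx(89 / np.sqrt(110))


def test_no_enrichment_rejected():
    # a = b gives z <= 0 regardless of magnitude
    assert pk._zscore(50, 50) < 0


def test_candidate_peaks_finds_planted_cluster(rng):
    cluster = rng.normal(3000, 10, size=200).astype(int)
    track = _track(cluster)
    empty = _track([])
    peaks = pk.candidate_peaks(track, empty, z_min=4.0, chip_size=200, input_size=100)
    assert len(peaks) == 1
    assert abs(peaks[0].location - 3000) <= 10
    assert peaks[0].z > 4


def test_candidate_peaks_zero_input_errors():
    track = _track([100])
    with pytest.raises(ValueError, match="input"):
        pk.candidate_peaks(track, _track([]), 4.0, chip_size=1, input_size=0)


def test_flat_null_track_rarely_yields_candidates():
    # Monte-Carlo null calibration: uniform tracks produce no z>=4
    # candidates in at least 99% of runs
    hits = 0
    n_runs = 100
    for seed in range(n_runs):
        r = np.random.default_rng(seed)
        chip = _track(r.integers(1, 20_000, size=40), length=20_000)
        inp = _track(r.integers(1, 20_000, size=200), length=20_000)
        if pk.candidate_peaks(chip, inp, 4.0, chip_size=40, input_size=200):
            hits += 1
    assert hits <= 1


def brute_candidates(chip_tags, input_tags, w, length, z_min, chip_size, input_size, tol=2):
    """Naive pure-python recomputation of the candidate-peak rules."""
    chip_tags = list(chip_tags)
    input_tags = list(input_tags)

    def cov(tags, x):
        if not 1 <= x <= length:
            return 0
        return sum(1 for t in tags if x - w <= t <= x + w)

    C = [0] + [cov(chip_tags, x) for x in range(1, length + 1)]
    filt = [
        max(C[max(x - w, 0) : min(x + w, length) + 1]) for x in range(length + 1)
    ]
    flagged = [
        x
        for x in range(1, length + 1)
        if C[x] >= filt[x] - tol and C[x] > 0 and filt[x] > tol
    ]
    runs = []
    for x in flagged:
        if runs and x == runs[-1][-1] + 1:
            runs[-1].append(x)
        else:
            runs.append([x])
    locs = []
    for run in runs:
        center = (run[0] + run[-1]) // 2
        window = [t for t in chip_tags if center - w <= t <= center + w and 1 <= t]
        if window:
            refined = round(sum(window) / len(window))
            center = min(max(refined, run[0]), run[-1])
        locs.append(center)
    merged = []
    for loc in locs:
        if merged and loc - merged[-1] < w:
            if C[loc] > C[merged[-1]]:
                merged[-1] = loc
        else:
            merged.append(loc)
    ratio = chip_size / input_size
    out = []
    for loc in merged:
        a = C[loc]
        flank = 0.5 * (cov(chip_tags, loc - 2 * w) + cov(chip_tags, loc + 2 * w))
        b = max(flank, cov(input_tags, loc) * ratio)
        z = (a - b - 1) / np.sqrt(a + b)
        if z >= z_min:
            out.append((loc, a, b))
    return out


def test_candidate_peaks_equal_brute_force_on_toy_replicon():
    # full-enumeration oracle on a 10-kb replicon with three clusters
    r = np.random.default_rng(42)
    chip_tags = np.concatenate(
        [
            r.normal(2000, 12, 60).astype(int),
            r.normal(5000, 12, 25).astype(int),
            r.normal(8000, 12, 90).astype(int),
            r.integers(1, 10_000, size=40),
        ]
    )
    input_tags = r.integers(1, 10_000, size=120)
    w, length = 100, 10_000
    chip_track = pk.CoverageTrack.from_positions(chip_tags, w, length)
    input_track = pk.CoverageTrack.from_positions(input_tags, w, length)
    fast = pk.candidate_peaks(chip_track, input_track, 4.0, chip_tags.size, input_tags.size)
    brute = brute_candidates(
        chip_tags, input_tags, w, length, 4.0, chip_tags.size, input_tags.size
    )
    assert [(p.location, p.a, p.b) for p in fast] == [
        (loc, float(a), float(b)) for loc, a, b in brute
    ]
    # the 25-tag middle cluster fails the z>=4 screen; the other two pass
    assert len(fast) == 2
    assert abs(fast[0].location - 2000) <= 10
    assert abs(fast[1].location - 8000) <= 10


# ---------------------------------------------------------------------------
# pairing


def _peak(location, z=10.0, strand="+"):
    return pk.StrandPeak("chr", strand, location, a=100.0, b=5.0, z=z)


def test_pair_peaks_basic_region_arithmetic():
    pairs = pk.pair_peaks([_peak(1000)], [_peak(1200, strand="-")], 50, 400)
    assert len(pairs) == 1
    region = pk._region_from_pair(*pairs[0])
    assert (region.start, region.end, region.location) == (1000, 1200, 1100)


def test_pair_peaks_reverse_upstream_only_no_region():
    pairs = pk.pair_peaks([_peak(1000)], [_peak(800, strand="-")], 50, 400)
    assert pairs == []


def test_pair_peaks_lag_bounds():
    assert pk.pair_peaks([_peak(1000)], [_peak(1030, strand="-")], 50, 400) == []
    assert pk.pair_peaks([_peak(1000)], [_peak(1500, strand="-")], 50, 400) == []
    with pytest.raises(ValueError):
        pk.pair_peaks([], [], 400, 50)


def brute_pair(fwd, rev, min_lag, max_lag):
    """Exhaustive-search pairing under the same greedy-by-z order."""
    available = set(range(len(rev)))
    pairs = []
    for i in sorted(range(len(fwd)), key=lambda i: (-fwd[i].z, fwd[i].location)):
        candidates = [
            (rev[j].location - fwd[i].location, j)
            for j in available
            if min_lag <= rev[j].location - fwd[i].location <= max_lag
        ]
        if candidates:
            _, j = min(candidates)
            available.discard(j)
            pairs.append((fwd[i], rev[j]))
    pairs.sort(key=lambda p: p[0].location)
    return pairs


def test_pair_peaks_matches_brute_force(rng):
    for _ in range(20):
        nf, nr = rng.integers(5, 11, size=2)
        fwd = [
            _peak(int(p), z=float(z))
            for p, z in zip(rng.integers(1, 5000, nf), rng.uniform(4, 20, nf))
        ]
        rev = [
            _peak(int(p), z=float(z), strand="-")
            for p, z in zip(rng.integers(1, 5000, nr), rng.uniform(4, 20, nr))
        ]
        fast = pk.pair_peaks(fwd, rev, 50, 400)
        brute = brute_pair(fwd, rev, 50, 400)
        assert [(f.location, r.location) for f, r in fast] == [
            (f.location, r.location) for f, r in brute
        ]


# ---------------------------------------------------------------------------
# scoring


def test_score_region_log_tail_matches_high_precision_oracle():
    import sympy

    z = 10.0
    log10_p = pk.log10_normal_sf(z)
    assert 10.0**log10_p == pytest.approx(7.62e-24, rel=1e-2)
    # 50-digit oracle: log10(erfc(z/sqrt(2))/2)
    expr = sympy.log(sympy.erfc(sympy.Rational(10) / sympy.sqrt(2)) / 2, 10)
    oracle = float(sympy.N(expr, 50))
    assert log10_p == pytest.approx(oracle, rel=1e-7)


def test_score_region_extreme_z_stays_finite():
    lp = pk.log10_normal_sf(200.0)
    assert np.isfinite(lp)
    assert lp == pytest.approx(-(200.0**2) / 2 / np.log(10), rel=1e-2)


def test_zero_peak_coverage_gives_nonsignificant_p():
    z = pk._zscore(0, 5)
    assert z <= 0
    assert pk.log10_normal_sf(z) >= np.log10(0.5) - 1e-12


def test_doubling_coverage_increases_z_pair():
    for a, b in [(10, 5), (100, 10), (7, 1)]:
        assert pk._zscore(2 * a, b) > pk._zscore(a, b)


def test_score_region_zero_total_errors():
    region = pk.BindingRegion(1, "chr", 100, 300, 200)
    empty = _track([], length=1000)
    with pytest.raises(ValueError):
        pk.score_region(region, empty, empty, empty, empty, 1, 1)


# ---------------------------------------------------------------------------
# Tarone-modified Benjamini-Yekutieli


def test_tarone_single_test():
    q = pk.tarone_by_qvalues([0.05], [0.0])
    assert q[0] == pytest.approx(0.05)


def test_tarone_hand_computation_all_included():
    # m=3, H(3)=11/6: raw q = p_k * 3 * (11/6) / k
    q = pk.tarone_by_qvalues([0.01, 0.02, 0.03], [0.0, 0.0, 0.0])
    assert q == pytest.approx([0.055, 0.055, 0.055])


def test_tarone_exclusion_hand_computation():
    # at the first threshold only one test can attain p=0.001
    q = pk.tarone_by_qvalues([0.001, 0.5], [0.0005, 0.4])
    assert q[0] == pytest.approx(0.001)
    assert q[1] == pytest.approx(0.75)


def test_tarone_validates_inputs():
    with pytest.raises(ValueError):
        pk.tarone_by_qvalues([1.5], [0.0])
    with pytest.raises(ValueError):
        pk.tarone_by_qvalues([0.01], [0.5])
    with pytest.raises(ValueError):
        pk.tarone_by_log10_qvalues(np.array([-1.0, -2.0]), np.array([-3.0]))


def test_tarone_reduces_to_standard_by(rng):
    # with all minp=0 the procedure is exactly Benjamini-Yekutieli
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(1e-6, 1, size=200)
    ours = pk.tarone_by_qvalues(p, np.zeros_like(p))
    _, theirs, _, _ = multipletests(p, method="fdr_by")
    np.testing.assert_allclose(ours, theirs, rtol=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=30)
)
def test_tarone_q_monotone_in_p(p_list):
    p = np.array(p_list)
    q = pk.tarone_by_qvalues(p, np.zeros_like(p))
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q <= 1 + 1e-12)


def test_tarone_log_space_survives_extreme_p():
    lp = np.array([-8000.0, -3.0, -1.0])
    lq = pk.tarone_by_log10_qvalues(lp, np.full(3, -9000.0))
    assert np.isfinite(lq).all()
    assert lq[0] < -7000


# ---------------------------------------------------------------------------
# end-to-end


def test_call_binding_regions_empty_chip():
    chip = TagLibrary("chip", {"chr": (np.array([]), np.array([]))})
    inp = TagLibrary("input", {"chr": (np.array([100, 200]), np.array([300]))})
    assert pk.call_binding_regions(chip, inp) == []


def test_call_binding_regions_empty_input_errors():
    chip = TagLibrary("chip", {"chr": (np.array([100]), np.array([300]))})
    inp = TagLibrary("input", {"chr": (np.array([]), np.array([]))})
    with pytest.raises(ValueError, match="input"):
        pk.call_binding_regions(chip, inp)


def test_call_binding_regions_small_dataset(small_dataset):
    regions = pk.call_binding_regions(
        small_dataset["chip"],
        small_dataset["input"],
        lengths=small_dataset["genome"].lengths,
    )
    truth = small_dataset["truth"]
    assert regions, "no regions called on a planted dataset"
    # sorted by NLQ descending
    nlqs = [r.nlq for r in regions]
    assert nlqs == sorted(nlqs, reverse=True)
    for r in regions:
        assert r.start <= r.location <= r.end
        assert r.midpoint == (r.start + r.end) // 2
        assert np.isfinite(r.nlq) and r.nlq >= 0
        assert r.q <= 0.05 + 1e-12
    # strong sites are recovered
    for site in truth.sites:
        if site.strength >= 50:
            err = min(abs(r.location - site.center) for r in regions)
            assert err <= 25


def test_nlq_ranking_consistent_with_p(small_dataset):
    regions = pk.call_binding_regions(
        small_dataset["chip"],
        small_dataset["input"],
        lengths=small_dataset["genome"].lengths,
    )
    # NLQ = -log10 Q is strictly decreasing in Q; ranking by NLQ must agree
    # with ranking by ascending log10_p up to Q ties
    by_p = sorted(regions, key=lambda r: r.log10_p)
    by_nlq = sorted(regions, key=lambda r: -r.nlq)
    assert [round(r.nlq, 9) for r in by_p] == [round(r.nlq, 9) for r in by_nlq]


def test_minp_lower_bound_is_attainable_extreme():
    # minp is the p-value when the whole total lands in the peak
    total = 50.0
    lmin = pk._log10_minp(total)
    z_max = (total - 1) / np.sqrt(total)
    assert lmin == pytest.approx(norm.logsf(z_max) / np.log(10))
    assert lmin <= pk.log10_normal_sf(pk._zscore(30, 20))
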