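"""Double-strand peak calling with discrete-FDR correction.

Per-strand candidate peaks are local maxima of a +-w moving-sum coverage of
5'-tag positions, screened by a continuity-corrected one-sided score
z = (a - b - 1)/sqrt(a + b) against a background that is the larger of the
local flank coverage and the library-size-scaled input coverage. Forward
and reverse candidates are paired into regions, rescored on the summed
coverage at the two peak locations, and the resulting discrete p-values are
adjusted with a Tarone-modified distribution-free Benjamini-Yekutieli
procedure. All p/Q arithmetic is carried in log10 space so that extremely
significant regions keep a finite NLQ = -log10(Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.stats import norm

from .io import TagLibrary

__all__ = [
    "CoverageTrack",
    "StrandPeak",
    "BindingRegion",
    "PeakParams",
    "strand_coverage",
    "candidate_peaks",
    "pair_peaks",
    "score_region",
    "tarone_by_qvalues",
    "tarone_by_log10_qvalues",
    "log10_normal_sf",
    "call_binding_regions",
]

_LN10 = np.log(10.0)


def log10_normal_sf(z: float | np.ndarray) -> float | np.ndarray:
    """log10 of the upper standard-normal tail, stable for very large z."""
    return norm.logsf(z) / _LN10


@dataclass
class CoverageTrack:
    """Dense moving-sum coverage C(x) = #{tags with 5' position in [x-w, x+w]}."""

    replicon: str
    strand: str
    w: int
    length: int
    raw: np.ndarray = field(repr=False)  # per-position tag counts, index 0 unused
    C: np.ndarray = field(repr=False)  # moving sum, index 0 unused

    @classmethod
    def from_positions(
        cls, positions: np.ndarray, w: int, length: int, replicon: str = "chr", strand: str = "+"
    ) -> "CoverageTrack":
        if w <= 0:
            raise ValueError(f"window half-width must be positive, got {w}")
        raw = np.bincount(np.asarray(positions, dtype=np.int64), minlength=length + 1)
        if raw.size > length + 1:
            raise ValueError("tag position beyond replicon length")
        cum = np.concatenate([[0], np.cumsum(raw)])
        x = np.arange(length + 1)
        hi = np.minimum(x + w, length)
        lo = np.maximum(x - w, 0)
        C = cum[hi + 1] - cum[lo]
        C[0] = 0
        return cls(replicon=replicon, strand=strand, w=w, length=length, raw=raw, C=C)

    def count(self, x: int | np.ndarray) -> int | np.ndarray:
        """C at position(s) x (1-based); positions outside [1, length] count 0."""
        x = np.asarray(x)
        inside = (x >= 1) & (x <= self.length)
        out = np.where(inside, self.C[np.clip(x, 0, self.length)], 0)
        if out.ndim == 0:
            return int(out)
        return out

    @property
    def tag_count(self) -> int:
        return int(self.raw.sum())


def strand_coverage(
    tags: TagLibrary, w: int, lengths: dict[str, int] | None = None
) -> dict[str, dict[str, CoverageTrack]]:
    """Coverage tracks per replicon and strand for a tag library."""
    if w <= 0:
        raise ValueError(f"window half-width must be positive, got {w}")
    tracks: dict[str, dict[str, CoverageTrack]] = {}
    for name, (fwd, rev) in tags.tags.items():
        if lengths is not None and name in lengths:
            length = lengths[name]
        else:
            top = max(
                int(fwd[-1]) if fwd.size else 0, int(rev[-1]) if rev.size else 0
            )
            length = top + 2 * w
        tracks[name] = {
            "+": CoverageTrack.from_positions(fwd, w, length, name, "+"),
            "-": CoverageTrack.from_positions(rev, w, length, name, "-"),
        }
    return tracks


@dataclass
class StrandPeak:
    """Local coverage maximum on one strand with its background expectation."""

    replicon: str
    strand: str
    location: int
    a: float  # center coverage
    b: float  # background expectation
    z: float


@dataclass
class BindingRegion:
    """A paired forward/reverse peak region in 1-based inclusive coordinates."""

    id: int
    replicon: str
    start: int  # forward peak location
    end: int  # reverse peak location
    location: int  # floor of the mean of the two peak locations
    z_pair: float = np.nan
    log10_p: float = np.nan
    log10_q: float = np.nan
    a_pair: float = np.nan
    b_pair: float = np.nan

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def q(self) -> float:
        return float(10.0**self.log10_q)

    @property
    def nlq(self) -> float:
        return float(-self.log10_q)


@dataclass
class PeakParams:
    """Tunable parameters of the double-strand peak caller."""

    w: int = 100
    z_min: float = 4.0
    min_lag: int = 50
    max_lag: int = 400
    fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.min_lag >= self.max_lag:
            raise ValueError("min_lag must be < max_lag")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")


def _background(
    chip: CoverageTrack, input_: CoverageTrack, loc: int, ratio: float
) -> float:
    w = chip.w
    flank = 0.5 * (chip.count(loc - 2 * w) + chip.count(loc + 2 * w))
    scaled_input = input_.count(loc) * ratio
    return float(max(flank, scaled_input))


def _zscore(a: float, b: float) -> float:
    total = a + b
    if total <= 0:
        raise ValueError("a + b must be positive")
    return (a - b - 1.0) / np.sqrt(total)


def candidate_peaks(
    chip: CoverageTrack,
    input_: CoverageTrack,
    z_min: float,
    chip_size: int,
    input_size: int,
    plateau_tol: int = 2,
) -> list[StrandPeak]:
    """Local maxima of ChIP coverage passing the one-sided z screen.

    The moving sum over a compact tag cluster has a near-flat top (width
    about 2w minus the cluster span) that background tags perturb by a
    count or two, so positions within ``plateau_tol`` of the windowed
    maximum are treated as one plateau. Each plateau collapses to the mean
    tag position inside the window (clamped into the plateau); maxima
    closer than w keep only the one with the higher center coverage
    (leftmost on ties).
    """
    if input_size <= 0:
        raise ValueError("input library is empty")
    if (chip.replicon, chip.strand) != (input_.replicon, input_.strand):
        raise ValueError("chip/input track mismatch")
    w = chip.w
    C = chip.C
    if C[1:].max(initial=0) == 0:
        return []
    filt = maximum_filter1d(C, size=2 * w + 1, mode="constant", cval=0)
    is_max = (C >= filt - plateau_tol) & (C > 0) & (filt > plateau_tol)
    is_max[0] = False
    idx = np.flatnonzero(is_max)
    if idx.size == 0:
        return []
    # collapse contiguous runs of equal-count maxima to their center
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [idx.size - 1]])
    # refine each plateau to the mean tag position inside the window,
    # clamped into the plateau so it stays a local maximum of C
    cum_cnt = np.concatenate([[0], np.cumsum(chip.raw)])
    cum_pos = np.concatenate(
        [[0], np.cumsum(chip.raw * np.arange(chip.raw.size, dtype=np.int64))]
    )
    locs = []
    for s, e in zip(run_starts, run_ends):
        lo_run, hi_run = int(idx[s]), int(idx[e])
        center = (lo_run + hi_run) // 2
        lo = max(center - w, 1)
        hi = min(center + w, chip.length)
        cnt = cum_cnt[hi + 1] - cum_cnt[lo]
        if cnt > 0:
            refined = int(round((cum_pos[hi + 1] - cum_pos[lo]) / cnt))
            center = min(max(refined, lo_run), hi_run)
        locs.append(center)
    # merge maxima closer than w, keeping the higher center count
    merged: list[int] = []
    for loc in locs:
        if merged and loc - merged[-1] < w:
            if C[loc] > C[merged[-1]]:
                merged[-1] = loc
        else:
            merged.append(loc)
    ratio = chip_size / input_size
    peaks: list[StrandPeak] = []
    for loc in merged:
        a = float(C[loc])
        b = _background(chip, input_, loc, ratio)
        z = _zscore(a, b)
        if z >= z_min:
            peaks.append(
                StrandPeak(chip.replicon, chip.strand, loc, a=a, b=b, z=z)
            )
    return peaks


def pair_peaks(
    fwd: Sequence[StrandPeak],
    rev: Sequence[StrandPeak],
    min_lag: int,
    max_lag: int,
) -> list[tuple[StrandPeak, StrandPeak]]:
    """Greedy forward/reverse pairing by descending forward z.

    Each forward peak takes the nearest unused downstream reverse peak whose
    lag lies in [min_lag, max_lag]; unmatched peaks are dropped.
    """
    if min_lag >= max_lag:
        raise ValueError("min_lag must be < max_lag")
    used = [False] * len(rev)
    pairs: list[tuple[StrandPeak, StrandPeak]] = []
    order = sorted(range(len(fwd)), key=lambda i: (-fwd[i].z, fwd[i].location))
    for i in order:
        f = fwd[i]
        best_j = -1
        best_lag = None
        for j, r in enumerate(rev):
            if used[j]:
                continue
            lag = r.location - f.location
            if min_lag <= lag <= max_lag and (best_lag is None or lag < best_lag):
                best_lag = lag
                best_j = j
        if best_j >= 0:
            used[best_j] = True
            pairs.append((f, rev[best_j]))
    pairs.sort(key=lambda p: p[0].location)
    return pairs


def _region_from_pair(fwd: StrandPeak, rev: StrandPeak, region_id: int = 0) -> BindingRegion:
    return BindingRegion(
        id=region_id,
        replicon=fwd.replicon,
        start=fwd.location,
        end=rev.location,
        location=(fwd.location + rev.location) // 2,
    )


def score_region(
    region: BindingRegion,
    chip_fwd: CoverageTrack,
    chip_rev: CoverageTrack,
    input_fwd: CoverageTrack,
    input_rev: CoverageTrack,
    chip_size: int,
    input_size: int,
) -> BindingRegion:
    """Score a paired region on the summed coverage at its two peak locations."""
    ratio = chip_size / input_size
    a_pair = float(chip_fwd.count(region.start) + chip_rev.count(region.end))
    b_pair = _background(chip_fwd, input_fwd, region.start, ratio) + _background(
        chip_rev, input_rev, region.end, ratio
    )
    if a_pair + b_pair <= 0:
        raise ValueError("region has zero total coverage")
    region.a_pair = a_pair
    region.b_pair = b_pair
    region.z_pair = _zscore(a_pair, b_pair)
    region.log10_p = float(log10_normal_sf(region.z_pair))
    return region


# ---------------------------------------------------------------------------
# Tarone-modified distribution-free Benjamini-Yekutieli


def tarone_by_log10_qvalues(
    log10_p: np.ndarray, log10_minp: np.ndarray
) -> np.ndarray:
    """Log-space Tarone-modified Benjamini-Yekutieli adjustment.

    For sorted p-values p_(1) <= ... <= p_(n), only tests whose smallest
    attainable p-value (minp) does not exceed p_(k) count toward the k-th
    threshold: with m_k = #{j : minp_j <= p_(k)} and H the harmonic number,
    raw q_(k) = p_(k) * m_k * H(m_k) / k, and Q_(k) is the step-down minimum
    over l >= k, capped at 1. Returns log10(Q) in the input order.
    """
    lp = np.asarray(log10_p, dtype=float)
    lmin = np.asarray(log10_minp, dtype=float)
    if lp.shape != lmin.shape:
        raise ValueError("p and minp lists must have equal length")
    if np.any(lp > 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(lmin > lp + 1e-12):
        raise ValueError("minp must not exceed p for any test")
    n = lp.size
    if n == 0:
        return np.empty(0)
    order = np.argsort(lp, kind="stable")
    lp_sorted = lp[order]
    m = np.searchsorted(np.sort(lmin), lp_sorted, side="right")
    harmonic = np.cumsum(1.0 / np.arange(1, n + 1))
    k = np.arange(1, n + 1)
    log_raw = lp_sorted + np.log10(m * harmonic[m - 1] / k)
    log_q_sorted = np.minimum.accumulate(log_raw[::-1])[::-1]
    log_q_sorted = np.minimum(log_q_sorted, 0.0)
    out = np.empty(n)
    out[order] = log_q_sorted
    return out


def tarone_by_qvalues(
    p_list: Sequence[float], minp_list: Sequence[float]
) -> np.ndarray:
    """Linear-scale convenience wrapper around the log-space adjustment."""
    p = np.asarray(p_list, dtype=float)
    minp = np.asarray(minp_list, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(minp > p + 1e-15):
        raise ValueError("minp must not exceed p for any test")
    with np.errstate(divide="ignore"):
        return 10.0 ** tarone_by_log10_qvalues(np.log10(p), np.log10(minp))


def _log10_minp(total: float) -> float:
    """Smallest attainable log10 p for a test with observed total count.

    Taken at the most extreme outcome: all of the total in the peak
    (a = total, b = 0), the discrete lower bound the Tarone step needs.
    """
    if total <= 0:
        return 0.0
    z_max = (total - 1.0) / np.sqrt(total)
    return float(log10_normal_sf(z_max))


# ---------------------------------------------------------------------------
# orchestration


def call_binding_regions(
    chip: TagLibrary,
    input_: TagLibrary,
    params: PeakParams | None = None,
    lengths: dict[str, int] | None = None,
) -> list[BindingRegion]:
    """Full pipeline: coverage -> candidates -> pairing -> scoring -> Q/NLQ.

    Returns regions with Q <= params.fdr, sorted by NLQ descending, with ids
    assigned in genome order before filtering.
    """
    params = params or PeakParams()
    if input_.library_size == 0:
        raise ValueError("input library is empty")
    chip_size = chip.library_size
    input_size = input_.library_size
    if chip_size == 0:
        return []
    chip_cov = strand_coverage(chip, params.w, lengths)
    shared_lengths = {
        name: tracks["+"].length for name, tracks in chip_cov.items()
    }
    input_cov = strand_coverage(input_, params.w, {**shared_lengths, **(lengths or {})})

    regions: list[BindingRegion] = []
    for name in chip.tags:
        cf, cr = chip_cov[name]["+"], chip_cov[name]["-"]
        if name in input_cov:
            inf, inr = input_cov[name]["+"], input_cov[name]["-"]
        else:
            inf = CoverageTrack.from_positions(
                np.empty(0, dtype=np.int64), params.w, cf.length, name, "+"
            )
            inr = CoverageTrack.from_positions(
                np.empty(0, dtype=np.int64), params.w, cr.length, name, "-"
            )
        fwd = candidate_peaks(cf, inf, params.z_min, chip_size, input_size)
        rev = candidate_peaks(cr, inr, params.z_min, chip_size, input_size)
        for f, r in pair_peaks(fwd, rev, params.min_lag, params.max_lag):
            region = _region_from_pair(f, r)
            score_region(region, cf, cr, inf, inr, chip_size, input_size)
            regions.append(region)

    if not regions:
        return []
    # genome-order ids over all paired regions, then FDR filter
    replicon_order = {name: i for i, name in enumerate(chip.tags)}
    regions.sort(key=lambda r: (replicon_order[r.replicon], r.start, r.end))
    for i, r in enumerate(regions, start=1):
        r.id = i
    log10_p = np.array([r.log10_p for r in regions])
    log10_minp = np.array([_log10_minp(r.a_pair + r.b_pair) for r in regions])
    log10_minp = np.minimum(log10_minp, log10_p)
    log10_q = tarone_by_log10_qvalues(log10_p, log10_minp)
    for r, lq in zip(regions, log10_q):
        r.log10_q = float(lq)
    kept = [r for r in regions if r.log10_q <= np.log10(params.fdr)]
    kept.sort(key=lambda r: (-r.nlq, r.id))
    return kept
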