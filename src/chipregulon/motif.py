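"""Degenerate GTAN8TAC site scanning, enrichment, and consensus matrices.

A site is a 14-mer window scored 0-6 by how many of the six constrained
positions (G1, T2, A3, T12, A13, C14) match; the 8-nt spacer is always
free. The constrained positions are reverse-complement palindromic, so
strict (score 6) hits coincide on the two strands as genomic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Genome, revcomp

__all__ = [
    "MotifSite",
    "PFMatrix",
    "score_window",
    "scan_sites",
    "scan_genome",
    "best_site_in_region",
    "motif_enrichment",
    "build_pfm",
    "extended_site_sequences",
]

SITE_LEN = 14
#: 0-based constrained offsets of the oriented consensus
CORE = {0: "G", 1: "T", 2: "A", 11: "T", 12: "A", 13: "C"}


@dataclass(frozen=True)
class MotifSite:
    """One 14-mer match, located by its leftmost genomic base (1-based)."""

    replicon: str
    start: int
    strand: str
    sequence: str  # oriented 5'->3' on `strand`
    score: int

    def __post_init__(self) -> None:
        if len(self.sequence) != SITE_LEN:
            raise ValueError("site sequence must be 14 nt")
        if not 0 <= self.score <= 6:
            raise ValueError("score must lie in 0..6")

    @property
    def end(self) -> int:
        return self.start + SITE_LEN - 1

    @property
    def center(self) -> float:
        """Genomic center of the 14-mer (half-integer)."""
        return self.start + (SITE_LEN - 1) / 2

    def three_prime_end(self) -> int:
        """Genomic position of the oriented 3'-terminal base."""
        return self.end if self.strand == "+" else self.start


def score_window(window: str) -> int:
    """Matches among the six constrained positions; N never matches."""
    if len(window) != SITE_LEN:
        raise ValueError("window must be 14 nt")
    return sum(1 for i, base in CORE.items() if window[i] == base)


def scan_sites(
    sequence: str,
    min_score: int = 5,
    both_strands: bool = True,
    require_g1: bool = False,
    replicon: str = "seq",
    offset: int = 0,
) -> list[MotifSite]:
    """All 14-mer windows scoring >= min_score on the requested strand(s).

    ``offset`` shifts reported starts (useful when the sequence is a slice
    of a larger replicon). A perfectly palindromic window would produce an
    identical hit on both strands; it is reported once, on the + strand.
    """
    if len(sequence) < SITE_LEN:
        raise ValueError("sequence shorter than 14 nt")
    sequence = sequence.upper()
    sites: list[MotifSite] = []
    for i in range(len(sequence) - SITE_LEN + 1):
        window = sequence[i : i + SITE_LEN]
        start = offset + i + 1
        fwd_score = score_window(window)
        fwd_hit = fwd_score >= min_score and (not require_g1 or window[0] == "G")
        if fwd_hit:
            sites.append(MotifSite(replicon, start, "+", window, fwd_score))
        if both_strands:
            rc = revcomp(window)
            rev_score = score_window(rc)
            if rev_score >= min_score and (not require_g1 or rc[0] == "G"):
                if fwd_hit and rc == window:
                    continue  # palindromic duplicate of the + hit
                sites.append(MotifSite(replicon, start, "-", rc, rev_score))
    return sites


def scan_genome(
    genome: Genome,
    min_score: int = 5,
    both_strands: bool = True,
    require_g1: bool = False,
) -> list[MotifSite]:
    sites: list[MotifSite] = []
    for name, seq in genome.replicons.items():
        if len(seq) >= SITE_LEN:
            sites.extend(
                scan_sites(seq, min_score, both_strands, require_g1, replicon=name)
            )
    return sites


def best_site_in_region(
    region_sequence: str,
    min_score: int = 5,
    both_strands: bool = True,
    require_g1: bool = False,
    replicon: str = "seq",
    offset: int = 0,
) -> MotifSite | None:
    """Highest-scoring site; ties go to the window nearest the region
    midpoint, then leftmost."""
    sites = scan_sites(
        region_sequence, min_score, both_strands, require_g1, replicon, offset
    )
    if not sites:
        return None
    mid = offset + (1 + len(region_sequence)) / 2
    return min(sites, key=lambda s: (-s.score, abs(s.center - mid), s.start, s.strand))


def motif_enrichment(
    regions: Sequence[tuple[str, int, int]],
    genome: Genome,
    n_controls: int,
    seed: int,
    min_score: int = 6,
) -> tuple[float, float]:
    """Strict-site density in regions versus length-matched random controls.

    ``regions`` are (replicon, start, end) 1-based inclusive intervals.
    Returns (enrichment ratio, empirical p = fraction of control sets with
    density >= observed). A universe with no qualifying site at all yields
    ratio 0 and p 1.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths

    def density(intervals: Iterable[tuple[str, int, int]]) -> float:
        total_bp = 0
        hits = 0
        for name, start, end in intervals:
            if start < 1 or end > lengths[name]:
                raise ValueError(f"region {name}:{start}-{end} out of bounds")
            seq = genome.fetch(name, start, end)
            total_bp += len(seq)
            if len(seq) >= SITE_LEN:
                hits += len(scan_sites(seq, min_score=min_score, both_strands=True))
        return hits / total_bp if total_bp else 0.0

    observed = density(regions)
    control_densities = np.empty(n_controls)
    for c in range(n_controls):
        controls = []
        for name, start, end in regions:
            span = end - start + 1
            span = min(span, lengths[name])
            s = int(rng.integers(1, lengths[name] - span + 2))
            controls.append((name, s, s + span - 1))
        control_densities[c] = density(controls)
    mean_control = float(control_densities.mean())
    if observed == 0.0:
        return 0.0, 1.0
    ratio = float("inf") if mean_control == 0.0 else observed / mean_control
    p = float(np.mean(control_densities >= observed))
    return ratio, p


@dataclass
class PFMatrix:
    """Position-frequency matrix with per-column information content."""

    counts: pd.DataFrame  # columns 1..L (1-based), index A/C/G/T
    n: int

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n

    @property
    def information(self) -> np.ndarray:
        """Bits per column: 2 + sum_b f_b log2 f_b (0 log 0 = 0)."""
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + terms.sum(axis=0)

    @property
    def length(self) -> int:
        return self.counts.shape[1]


def build_pfm(sequences: Sequence[str], extend: int = 0) -> PFMatrix:
    """Count matrix over aligned equal-length sequences.

    ``extend`` declares the expected flank on each side of the 14-nt core;
    sequences must have length 14 + 2*extend.
    """
    if not sequences:
        raise ValueError("no sequences")
    expected = SITE_LEN + 2 * extend
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must be equal length")
    if length != expected:
        raise ValueError(f"expected length {expected} for extend={extend}, got {length}")
    counts = pd.DataFrame(
        0, index=list("ACGT"), columns=range(1, length + 1), dtype=int
    )
    for s in sequences:
        for j, base in enumerate(s.upper(), start=1):
            if base in "ACGT":
                counts.loc[base, j] += 1
    return PFMatrix(counts=counts, n=len(sequences))


def extended_site_sequences(
    sites: Sequence[MotifSite], genome: Genome, extend: int = 6
) -> list[str]:
    """Oriented site sequences with `extend` genomic nt on each side.

    Sites too close to a replicon edge for the full flank are skipped.
    """
    out = []
    for s in sites:
        lo = s.start - extend
        hi = s.end + extend
        if lo < 1 or hi > genome.lengths[s.replicon]:
            continue
        seq = genome.fetch(s.replicon, lo, hi)
        out.append(seq if s.strand == "+" else revcomp(seq))
    return out
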