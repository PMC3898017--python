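"""Promoter-architecture classification of motif sites.

Distance conventions: the spacer to the -10 box counts intervening bases
only (exclusive), while the distance to the transcription start point (TSP)
counts intervening bases plus the TSP base itself. For a 14-nt site the
site-center-to-TSP distance is tsp_distance + 6.5, so the canonical Class II
geometry (22-nt spacer, 6-nt TAN3T box, 6 intervening nt, TSP) puts the
site center 41.5 nt upstream of the TSP.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .io import Genome, revcomp
from .motif import SITE_LEN, MotifSite

__all__ = [
    "PromoterClass",
    "TSPRecord",
    "PromoterCall",
    "ArchParams",
    "find_minus10",
    "site_tsp_distance",
    "classify_promoter",
]

BOX_LEN = 6


class PromoterClass(str, Enum):
    CLASS_II_ACTIVATOR = "CLASS_II_ACTIVATOR"
    REPRESSOR_LIKE = "REPRESSOR_LIKE"
    SITE_ONLY = "SITE_ONLY"


@dataclass(frozen=True)
class TSPRecord:
    """A transcription start point (+1 base), 1-based."""

    replicon: str
    position: int
    strand: str
    regulation: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.regulation not in {"induced", "repressed", "unknown"}:
            raise ValueError(f"invalid regulation {self.regulation!r}")


@dataclass
class PromoterCall:
    site: MotifSite
    promoter_class: PromoterClass
    minus10: str | None = None
    minus10_spacer: int | None = None  # intervening nt, exclusive
    tsp: TSPRecord | None = None
    tsp_distance: int | None = None  # counts the TSP base
    center_to_tsp: float | None = None  # tsp_distance + 6.5


@dataclass
class ArchParams:
    spacer_min: int = 20
    spacer_max: int = 24
    tsp_distance_min: int = 30
    tsp_distance_max: int = 40
    repressor_upstream: int = 35  # site may begin this far upstream of the TSP
    repressor_downstream: int = 15


def _is_tan3t(box: str) -> bool:
    return (
        len(box) == BOX_LEN
        and box[0] == "T"
        and box[1] == "A"
        and box[5] == "T"
        and "N" not in (box[0], box[1], box[5])
    )


def find_minus10(
    downstream: str, spacer_window: tuple[int, int] = (20, 24)
) -> tuple[int, str] | None:
    """First TAN3T hexamer whose exclusive spacer lies in the window.

    ``downstream`` is the oriented sequence immediately 3' of the site;
    returns (spacer, hexamer) or None. Matches with shorter spacers outside
    the window are ignored.
    """
    lo, hi = spacer_window
    if lo < 0 or lo > hi:
        raise ValueError(f"invalid spacer window {spacer_window}")
    for spacer in range(lo, hi + 1):
        box = downstream[spacer : spacer + BOX_LEN]
        if _is_tan3t(box):
            return spacer, box
    return None


def site_tsp_distance(site: MotifSite, tsp: TSPRecord) -> tuple[int, float]:
    """Strand-aware distance from the site 3' end to the TSP.

    Counts the intervening bases plus the TSP base itself; a TSP upstream of
    the site 3' end gives a negative distance (reported, not an error).
    Returns (tsp_distance, center_to_tsp).
    """
    end3 = site.three_prime_end()
    if site.strand == "+":
        distance = tsp.position - end3
    else:
        distance = end3 - tsp.position
    return distance, distance + (SITE_LEN - 1) / 2

def _downstream_sequence(site: MotifSite, genome: Genome, span: int) -> str:
    if site.strand == "+":
        return genome.fetch(site.replicon, site.end + 1, site.end + span)
    lo = max(1, site.start - span)
    return revcomp(genome.fetch(site.replicon, lo, site.start - 1))


def classify_promoter(
    site: MotifSite,
    genome: Genome,
    tsps: Sequence[TSPRecord] | None = None,
    params: ArchParams | None = None,
) -> PromoterCall:
    """Classify a site as Class II activator, repressor-like, or site-only.

    Class II requires a TAN3T box in the spacer window and, when a TSP list
    is supplied, a same-strand TSP at a canonical distance. Without Class II
    geometry, a site whose 14-mer overlaps the promoter window around a
    same-strand TSP is called repressor-like.
    """
    params = params or ArchParams()
    span = params.spacer_max + BOX_LEN
    downstream = _downstream_sequence(site, genome, span)
    box_hit = find_minus10(downstream, (params.spacer_min, params.spacer_max))

    same_strand = [
        t
        for t in (tsps or [])
        if t.replicon == site.replicon and t.strand == site.strand
    ]
    best_tsp: TSPRecord | None = None
    best_distance: int | None = None
    for t in same_strand:
        d, _ = site_tsp_distance(site, t)
        if best_distance is None or abs(d) < abs(best_distance):
            best_tsp, best_distance = t, d

    call = PromoterCall(site=site, promoter_class=PromoterClass.SITE_ONLY)
    if box_hit is not None:
        call.minus10_spacer, call.minus10 = box_hit

    canonical_tsp = None
    canonical_distance = None
    for t in same_strand:
        d, _ = site_tsp_distance(site, t)
        if params.tsp_distance_min <= d <= params.tsp_distance_max:
            if canonical_distance is None or abs(d - 35) < abs(canonical_distance - 35):
                canonical_tsp, canonical_distance = t, d

    if box_hit is not None and (not tsps or canonical_tsp is not None):
        call.promoter_class = PromoterClass.CLASS_II_ACTIVATOR
        chosen = canonical_tsp if canonical_tsp is not None else best_tsp
        if chosen is not None:
            call.tsp = chosen
            call.tsp_distance, call.center_to_tsp = site_tsp_distance(site, chosen)
        return call

    # repressor-like: the 14-mer overlaps [TSP - up, TSP + down] in the
    # TSP's reading direction
    for t in same_strand:
        if t.strand == "+":
            lo = t.position - params.repressor_upstream
            hi = t.position + params.repressor_downstream
        else:
            lo = t.position - params.repressor_downstream
            hi = t.position + params.repressor_upstream
        if site.start <= hi and site.end >= lo:
            call.promoter_class = PromoterClass.REPRESSOR_LIKE
            call.tsp = t
            call.tsp_distance, call.center_to_tsp = site_tsp_distance(site, t)
            return call

    if best_tsp is not None:
        call.tsp = best_tsp
        call.tsp_distance, call.center_to_tsp = site_tsp_distance(site, best_tsp)
    return call
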