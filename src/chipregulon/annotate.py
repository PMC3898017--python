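"""Region-to-gene assignment, positional classification, and summaries.

The anchor of every region is its midpoint. A region is ascribed to the
gene containing the anchor, or else to nearby genes whose (strand-aware)
5' start lies within ``d_up`` of the anchor or whose 3' end lies within
``d_down``. Two genes are reported when two candidates tie and an optional
differential-expression table cannot break the tie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, round_half_up

__all__ = [
    "PositionClass",
    "AssignParams",
    "GeneAssignment",
    "assign_region",
    "classify_position",
    "summarize_positions",
    "internal_share",
    "summarize_categories",
    "compare_site_lists",
    "qpcr_enrichment",
]


class PositionClass(str, Enum):
    UPSTREAM_FAR = "UPSTREAM_FAR"
    UPSTREAM_CLOSE = "UPSTREAM_CLOSE"
    INTERNAL_5 = "INTERNAL_5"
    INTERNAL_3 = "INTERNAL_3"
    DOWNSTREAM = "DOWNSTREAM"


#: collapse to the three table-level super-classes
SUPER_CLASS = {
    PositionClass.UPSTREAM_FAR: "Upstream",
    PositionClass.UPSTREAM_CLOSE: "Upstream",
    PositionClass.INTERNAL_5: "Internal",
    PositionClass.INTERNAL_3: "Internal",
    PositionClass.DOWNSTREAM: "Downstream",
}


@dataclass
class AssignParams:
    u_close: int = 200  # close-upstream cutoff
    d_up: int = 1500  # maximum upstream distance (long 5'-UTR allowance)
    d_down: int = 300  # maximum downstream distance
    tie_bp: int = 10  # candidates within this of the best distance tie


@dataclass
class GeneAssignment:
    region_id: int
    replicon: str
    gene_ids: list[str] = field(default_factory=list)
    position_classes: list[PositionClass] = field(default_factory=list)
    distances: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gene_ids) > 2:
            raise ValueError("at most two genes per assignment")
        if len(self.gene_ids) != len(self.position_classes):
            raise ValueError("one position class per listed gene")

    @property
    def assigned(self) -> bool:
        return bool(self.gene_ids)


def _upstream_gap(anchor: int, gene: GeneModel) -> int:
    """Bases between the anchor and the gene 5' start (positive if the
    anchor lies upstream of the gene, strand-aware)."""
    if gene.strand == "+":
        return gene.start - anchor
    return anchor - gene.end


def _downstream_gap(anchor: int, gene: GeneModel) -> int:
    """Bases past the gene 3' end (positive if the anchor lies downstream)."""
    if gene.strand == "+":
        return anchor - gene.end
    return gene.start - anchor


def classify_position(
    anchor: int, gene: GeneModel, params: AssignParams | None = None
) -> PositionClass:
    """Strand-aware positional class of an anchor with respect to a gene."""
    params = params or AssignParams()
    if gene.start <= anchor <= gene.end:
        offset5 = anchor - gene.start if gene.strand == "+" else gene.end - anchor
        # exact middle ties toward the 5' half
        if offset5 <= (gene.length - 1) / 2:
            return PositionClass.INTERNAL_5
        return PositionClass.INTERNAL_3
    up = _upstream_gap(anchor, gene)
    if 0 < up <= params.d_up:
        if up <= params.u_close:
            return PositionClass.UPSTREAM_CLOSE
        return PositionClass.UPSTREAM_FAR
    down = _downstream_gap(anchor, gene)
    if 0 < down <= params.d_down:
        return PositionClass.DOWNSTREAM
    raise ValueError(
        f"anchor {anchor} outside all windows of gene {gene.gene_id}"
    )


def _candidates(
    anchor: int, genes: Sequence[GeneModel], params: AssignParams
) -> list[tuple[int, int, GeneModel]]:
    """(rank, distance, gene) candidates; rank 0 = containment."""
    out = []
    for gene in genes:
        if gene.start <= anchor <= gene.end:
            out.append((0, 0, gene))
            continue
        up = _upstream_gap(anchor, gene)
        if 0 < up <= params.d_up:
            out.append((1, up, gene))
            continue
        down = _downstream_gap(anchor, gene)
        if 0 < down <= params.d_down:
            out.append((1, down, gene))
    return out


def assign_region(
    region,
    genes: Sequence[GeneModel],
    expression: Mapping[str, bool] | None = None,
    params: AssignParams | None = None,
) -> GeneAssignment:
    """Ascribe a binding region to one or two genes by its midpoint anchor.

    Containment beats proximity; an expression-flagged (differentially
    regulated) gene beats an unflagged one at equal rank; two genes are
    reported when the tie survives. Returns an empty (unassigned) record
    when no gene lies within the configured windows.
    """
    if not genes:
        raise ValueError("empty annotation")
    params = params or AssignParams()
    anchor = region.midpoint
    local = [g for g in genes if g.replicon == region.replicon]
    cands = _candidates(anchor, local, params)
    assignment = GeneAssignment(region_id=region.id, replicon=region.replicon)
    if not cands:
        return assignment
    cands.sort(key=lambda c: (c[0], c[1], c[2].gene_id))
    best_rank, best_dist, _ = cands[0]
    tied = [
        c
        for c in cands
        if c[0] == best_rank and c[1] - best_dist <= params.tie_bp
    ]
    if len(tied) > 1 and expression:
        flagged = [c for c in tied if expression.get(c[2].gene_id, False)]
        if len(flagged) == 1:
            tied = flagged
    chosen = tied[:2]
    for _rank, dist, gene in chosen:
        assignment.gene_ids.append(gene.gene_id)
        assignment.position_classes.append(classify_position(anchor, gene, params))
        assignment.distances.append(dist)
    return assignment


def summarize_positions(
    assignments: Iterable[GeneAssignment],
) -> pd.DataFrame:
    """Per-replicon counts of regions, distinct genes, and per-gene position
    super-classes, with a Total row and an integer internal percentage."""
    rows: dict[str, dict[str, object]] = {}
    for a in assignments:
        row = rows.setdefault(
            a.replicon,
            {"regions": 0, "genes": set(), "Upstream": 0, "Internal": 0, "Downstream": 0},
        )
        row["regions"] += 1
        for gene_id, pclass in zip(a.gene_ids, a.position_classes):
            row["genes"].add(gene_id)
            row[SUPER_CLASS[PositionClass(pclass)]] += 1
    records = []
    for name in sorted(rows):
        row = rows[name]
        records.append(
            {
                "replicon": name,
                "regions": row["regions"],
                "genes": len(row["genes"]),
                "Upstream": row["Upstream"],
                "Internal": row["Internal"],
                "Downstream": row["Downstream"],
            }
        )
    df = pd.DataFrame(
        records,
        columns=["replicon", "regions", "genes", "Upstream", "Internal", "Downstream"],
    )
    total = {
        "replicon": "Total",
        "regions": int(df["regions"].sum()) if len(df) else 0,
        "genes": len(set().union(*[rows[n]["genes"] for n in rows])) if rows else 0,
        "Upstream": int(df["Upstream"].sum()) if len(df) else 0,
        "Internal": int(df["Internal"].sum()) if len(df) else 0,
        "Downstream": int(df["Downstream"].sum()) if len(df) else 0,
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df["internal_pct"] = [
        internal_share(u, i, d) if (u + i + d) else np.nan
        for u, i, d in zip(df["Upstream"], df["Internal"], df["Downstream"])
    ]
    return df


def internal_share(upstream: int, internal: int, downstream: int) -> int:
    """Percentage of per-gene assignments classified Internal (nearest int)."""
    total = upstream + internal + downstream
    if total == 0:
        raise ValueError("no assignments")
    return int(round_half_up(100.0 * internal / total))


def summarize_categories(
    gene_ids: Iterable[str], categories: Mapping[str, str]
) -> pd.DataFrame:
    """Counts and one-decimal percentages of ascribed genes per functional
    category (each gene once; unmapped genes fall to "hypothetical")."""
    unique = sorted(set(gene_ids))
    total = len(unique)
    counts: dict[str, int] = {}
    for gid in unique:
        cat = categories.get(gid, "hypothetical")
        counts[cat] = counts.get(cat, 0) + 1
    df = pd.DataFrame(
        {
            "category": list(counts),
            "genes": [counts[c] for c in counts],
        }
    ).sort_values("genes", ascending=False, ignore_index=True)
    df["percent"] = [round_half_up(100.0 * c / total, 1) for c in df["genes"]]
    df.attrs["total_genes"] = total
    return df


@dataclass
class SiteListComparison:
    common: list[tuple[tuple[str, int], tuple[str, int], int]]
    found_only: list[tuple[str, int]]
    predicted_only: list[tuple[str, int]]


def compare_site_lists(
    found: Sequence[tuple[str, int]],
    predicted: Sequence[tuple[str, int]],
    tolerance: int = 50,
) -> SiteListComparison:
    """Greedy symmetric matching of two (replicon, position) site lists.

    Pairs within ``tolerance`` bp on the same replicon are matched in order
    of increasing distance, each site at most once.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    pairs = []
    for i, (rep_f, pos_f) in enumerate(found):
        for j, (rep_p, pos_p) in enumerate(predicted):
            if rep_f != rep_p:
                continue
            d = abs(pos_f - pos_p)
            if d <= tolerance:
                pairs.append((d, i, j))
    pairs.sort()
    used_f: set[int] = set()
    used_p: set[int] = set()
    common = []
    for d, i, j in pairs:
        if i in used_f or j in used_p:
            continue
        used_f.add(i)
        used_p.add(j)
        common.append((tuple(found[i]), tuple(predicted[j]), d))
    found_only = [tuple(s) for i, s in enumerate(found) if i not in used_f]
    predicted_only = [tuple(s) for j, s in enumerate(predicted) if j not in used_p]
    return SiteListComparison(common, found_only, predicted_only)


def qpcr_enrichment(ct_sample: float, ct_control: float) -> float:
    """Fold enrichment 2^(Ct_sample - Ct_control) of a region in the ChIP
    sample relative to the input control."""
    if not (np.isfinite(ct_sample) and np.isfinite(ct_control)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_sample - ct_control))
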