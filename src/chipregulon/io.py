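"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout the package; BED
(0-based, half-open) is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genome",
    "GeneModel",
    "TagLibrary",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_gff3",
    "read_tags_bed",
    "write_tags_bed",
    "write_region_table",
    "read_region_table",
    "bed_to_one_based",
    "one_based_to_bed",
    "round_half_up",
]

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with ties away from zero (table-style rounding)."""
    factor = 10.0**ndigits
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


def _normalize_sequence(raw: str) -> str:
    """Uppercase, map U->T, collapse any other IUPAC letter to N."""
    seq = raw.upper().replace("U", "T")
    if set(seq) - _ALLOWED:
        seq = "".join(c if c in _ALLOWED else "N" for c in seq)
    return seq


@dataclass
class Genome:
    """Ordered collection of replicon sequences (A/C/G/T/N, uppercase)."""

    replicons: dict[str, str]

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError("genome has no replicons")
        for name, seq in self.replicons.items():
            if not seq:
                raise ValueError(f"replicon {name!r} is empty")
            bad = set(seq) - _ALLOWED
            if bad:
                raise ValueError(f"replicon {name!r} has invalid letters {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.replicons.items()}

    def fetch(self, replicon: str, start: int, end: int) -> str:
        """Subsequence in 1-based inclusive coordinates, clipped to bounds."""
        seq = self.replicons[replicon]
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        return seq[max(start - 1, 0) : min(end, len(seq))]


@dataclass
class GeneModel:
    """A gene (or sRNA) feature in 1-based inclusive coordinates."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    product: str = ""
    category: str = "hypothetical"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start {self.start} < 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class TagLibrary:
    """Strand-separated 5'-end tag positions per replicon (1-based).

    ``tags`` maps replicon name to a ``(forward, reverse)`` pair of sorted
    integer arrays.
    """

    sample: str
    tags: dict[str, tuple[np.ndarray, np.ndarray]]
    lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.sample not in {"chip", "input"}:
            raise ValueError(f"sample must be 'chip' or 'input', got {self.sample!r}")
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (fwd, rev) in self.tags.items():
            fwd = np.sort(np.asarray(fwd, dtype=np.int64))
            rev = np.sort(np.asarray(rev, dtype=np.int64))
            for arr in (fwd, rev):
                if arr.size and arr[0] < 1:
                    raise ValueError(f"{name}: tag position < 1")
                if self.lengths is not None and arr.size and arr[-1] > self.lengths[name]:
                    raise ValueError(f"{name}: tag position beyond replicon end")
            clean[name] = (fwd, rev)
        self.tags = clean

    @property
    def library_size(self) -> int:
        return int(sum(f.size + r.size for f, r in self.tags.values()))


# ---------------------------------------------------------------------------
# coordinate conversion


def bed_to_one_based(chrom_start: int, chrom_end: int) -> tuple[int, int]:
    """BED 0-based half-open interval -> 1-based inclusive."""
    if chrom_start < 0 or chrom_end <= chrom_start:
        raise ValueError(f"invalid BED interval [{chrom_start}, {chrom_end})")
    return chrom_start + 1, chrom_end


def one_based_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> BED 0-based half-open."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval [{start}, {end}]")
    return start - 1, end


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a Genome (uppercase, U mapped to T)."""
    replicons: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in replicons:
            raise ValueError(f"duplicate record name {record.id!r}")
        replicons[record.id] = _normalize_sequence(str(record.seq))
    if not replicons:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(replicons)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.replicons.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or a headered TSV.

    Both dialects carry 1-based inclusive coordinates. Genes come back
    sorted by (replicon, start); a missing functional category defaults to
    "hypothetical".
    """
    if dialect == "gff3":
        genes = _read_gff3(path)
    elif dialect == "tsv":
        genes = _read_annotation_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    genes.sort(key=lambda g: (g.replicon, g.start, g.end))
    return genes


def _read_gff3(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
            if ftype not in {"gene", "CDS", "sRNA", "ncRNA"}:
                continue
            att = _parse_gff3_attributes(attrs)
            gene_id = att.get("ID") or att.get("locus_tag") or att.get("Name")
            if gene_id is None:
                raise ValueError(f"feature without ID in {path}: {line!r}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    replicon=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    product=att.get("product", ""),
                    category=att.get("category", "hypothetical"),
                )
            )
    return genes


def _read_annotation_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "replicon", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        category = getattr(row, "category", None)
        product = getattr(row, "product", None)
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                replicon=row.replicon,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                product="" if product is None or pd.isna(product) else str(product),
                category="hypothetical"
                if category is None or pd.isna(category)
                else str(category),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            if g.category:
                attrs += f";category={g.category}"
            fh.write(
                f"{g.replicon}\tchipregulon\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# tags (BED6)


def read_tags_bed(path: str | Path, sample: str) -> TagLibrary:
    """Read strand-annotated tag intervals from BED6.

    The 5' end of each interval becomes the tag position: chromStart+1 on
    the forward strand, chromEnd on the reverse strand (1-based).
    """
    fwd: dict[str, list[int]] = {}
    rev: dict[str, list[int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns (missing strand?)")
            chrom, cs, ce, _name, _score, strand = fields[:6]
            chrom_start, chrom_end = int(cs), int(ce)
            if chrom_start < 0:
                raise ValueError(f"{path}:{ln}: negative coordinate")
            start1, end1 = bed_to_one_based(chrom_start, chrom_end)
            if strand == "+":
                fwd.setdefault(chrom, []).append(start1)
                rev.setdefault(chrom, [])
            elif strand == "-":
                rev.setdefault(chrom, []).append(end1)
                fwd.setdefault(chrom, [])
            else:
                raise ValueError(f"{path}:{ln}: missing/invalid strand {strand!r}")
    tags = {name: (np.array(fwd[name]), np.array(rev[name])) for name in fwd}
    return TagLibrary(sample=sample, tags=tags)


def write_tags_bed(
    library: TagLibrary, path: str | Path, fragment_hint: int = 1
) -> None:
    """Write tag 5' positions as minimal BED6 single-base intervals."""
    with open(path, "w") as fh:
        for name, (fwd, rev) in library.tags.items():
            for pos in fwd:
                cs, ce = one_based_to_bed(int(pos), int(pos))
                fh.write(f"{name}\t{cs}\t{ce}\t.\t0\t+\n")
            for pos in rev:
                cs, ce = one_based_to_bed(int(pos), int(pos))
                fh.write(f"{name}\t{cs}\t{ce}\t.\t0\t-\n")


# ---------------------------------------------------------------------------
# region tables

_REGION_COLUMNS = [
    "region_id",
    "replicon",
    "start",
    "end",
    "midpoint",
    "location",
    "z_pair",
    "log10_p",
    "Q",
    "NLQ",
    "genes",
    "position_class",
    "site_sequence",
]

#: smallest Q rendered as a number; below this the Q column prints "0"
Q_RENDER_FLOOR = 1e-308


def format_q(log10_q: float) -> str:
    """Render a log10 Q value for the table ("0" below double precision)."""
    if log10_q < np.log10(Q_RENDER_FLOOR):
        return "0"
    return f"{10.0 ** log10_q:.6g}"


def write_region_table(
    regions: Sequence,
    assignments: Mapping[int, object] | None,
    sites: Mapping[int, object] | None,
    path: str | Path,
) -> pd.DataFrame:
    """Write the scored-region TSV plus a BED companion file.

    ``assignments`` and ``sites`` map region id to a GeneAssignment /
    MotifSite (either may be None). Raises if a mapping carries an id not
    present in ``regions``.
    """
    path = Path(path)
    region_ids = {r.id for r in regions}
    for label, mapping in (("assignments", assignments), ("sites", sites)):
        if mapping:
            stray = set(mapping) - region_ids
            if stray:
                raise ValueError(f"{label} carry unknown region ids {sorted(stray)}")
    rows = []
    for r in regions:
        assignment = assignments.get(r.id) if assignments else None
        site = sites.get(r.id) if sites else None
        genes = ";".join(assignment.gene_ids) if assignment and assignment.gene_ids else "."
        pclass = (
            ";".join(c.value if hasattr(c, "value") else str(c) for c in assignment.position_classes)
            if assignment and assignment.position_classes
            else "."
        )
        rows.append(
            {
                "region_id": r.id,
                "replicon": r.replicon,
                "start": r.start,
                "end": r.end,
                "midpoint": r.midpoint,
                "location": r.location,
                "z_pair": f"{r.z_pair:.4f}",
                "log10_p": f"{r.log10_p:.4f}",
                "Q": format_q(r.log10_q),
                "NLQ": f"{r.nlq:.2f}",
                "genes": genes,
                "position_class": pclass,
                "site_sequence": site.sequence if site else ".",
            }
        )
    df = pd.DataFrame(rows, columns=_REGION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    bed_path = path.with_suffix(".bed")
    with open(bed_path, "w") as fh:
        for r in regions:
            cs, ce = one_based_to_bed(r.start, r.end)
            fh.write(f"{r.replicon}\t{cs}\t{ce}\tregion_{r.id}\t{r.nlq:.2f}\t.\n")
    return df


def read_region_table(path: str | Path) -> pd.DataFrame:
    """Re-read a region TSV written by :func:`write_region_table`."""
    return pd.read_csv(path, sep="\t")
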