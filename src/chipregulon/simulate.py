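"""Synthetic genome, planted binding sites, and ChIP/input tag libraries.

The generator plants degenerate GTAN8TAC-style 14-mers (a mixture of
intragenic and intergenic placements), optionally writes canonical Class II
promoter geometry downstream of intergenic sites (TAN3T box after a 22-nt
spacer, transcription start 35 nt from the site 3' end), and simulates
fragment-end 5' tags: per site a Poisson number of fragment pairs centered
on the site with ~200-bp lengths, plus uniform per-strand background, plus
a uniform matched input library. Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Genome, GeneModel, TagLibrary, revcomp

__all__ = [
    "SimulationConfig",
    "SiteRecord",
    "SyntheticTruth",
    "generate_genome",
    "plant_sites",
    "simulate_tags",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))
#: oriented consensus constraints of the planted 14-mer (0-based offsets)
CORE = {0: "G", 1: "T", 2: "A", 11: "T", 12: "A", 13: "C"}
SITE_LEN = 14
#: canonical geometry (all distances from the site 3' end, 1-based sense)
BOX_SPACER = 22  # intervening nt before the TAN3T box
BOX_LEN = 6
TSP_OFFSET = 35  # distance to the TSP counting the TSP base
#: minimum distance between planted site centers, so neighbouring peaks
#: cannot merge under the default w=100 caller
MIN_SITE_SPACING = 600


@dataclass
class SimulationConfig:
    genome_length: int = 500_000
    n_genes: int = 400
    n_sites: int = 60
    frac_intragenic_sites: float = 0.65
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    strength_min: float = 20.0
    strength_max: float = 500.0
    background_rate: float = 0.002
    input_rate: float = 0.01
    site_mutation_rate: float = 0.1
    gene_length_min: int = 300
    gene_length_max: int = 3000
    min_gap: int = 50
    replicon: str = "chr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.frac_intragenic_sites <= 1:
            raise ValueError("frac_intragenic_sites must be in [0, 1]")
        for name in ("background_rate", "input_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.site_mutation_rate <= 1:
            raise ValueError("site_mutation_rate must be in [0, 1]")
        if self.strength_min <= 0 or self.strength_max < self.strength_min:
            raise ValueError("invalid strength range")


@dataclass
class SiteRecord:
    """Ground truth for one planted 14-mer site."""

    site_id: int
    replicon: str
    start: int  # 1-based leftmost genomic position of the 14-mer
    strand: str
    sequence: str  # oriented (reading 5'->3' on `strand`)
    strength: float
    intragenic: bool
    class_ii: bool = False
    box_start: int | None = None  # leftmost genomic position of the TAN3T box
    tsp: int | None = None  # genomic position of the planted TSP base

    @property
    def end(self) -> int:
        return self.start + SITE_LEN - 1

    @property
    def center(self) -> float:
        return self.start + (SITE_LEN - 1) / 2

    @property
    def is_strict(self) -> bool:
        return all(self.sequence[i] == b for i, b in CORE.items())


@dataclass
class SyntheticTruth:
    """Everything a recovery experiment needs to grade the pipeline."""

    replicon: str
    genome_length: int
    sites: list[SiteRecord]
    genes: list[GeneModel]
    tsps: list[tuple[str, int, str]]  # (replicon, position, strand)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_genome(config: SimulationConfig) -> tuple[Genome, list[GeneModel]]:
    """Uniform-composition genome with non-overlapping genes.

    Gene lengths are drawn uniformly from the configured range; if the
    requested complement cannot fit with the minimum intergenic gaps the
    lengths are shrunk proportionally (an error is raised only when even
    minimum-length genes do not fit).
    """
    rng = _rng(config, 0)
    L = config.genome_length
    seq = "".join(_BASES[rng.integers(0, 4, size=L)])
    genome = Genome({config.replicon: seq})
    n = config.n_genes
    if n == 0:
        return genome, []
    gap = config.min_gap
    min_needed = n * config.gene_length_min + (n + 1) * gap
    if min_needed > L:
        raise ValueError(
            f"genome of {L} bp too short for {n} genes of >= {config.gene_length_min} bp"
        )
    lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1, size=n)
    budget = L - (n + 1) * gap
    # keep ~15% of the budget intergenic so sites with promoter geometry fit
    target = int(budget * 0.85)
    if lengths.sum() > target and target >= n * config.gene_length_min:
        budget = target
    if lengths.sum() > budget:
        scale = budget / lengths.sum()
        lengths = np.maximum(config.gene_length_min, (lengths * scale).astype(int))
        excess = int(lengths.sum()) - budget
        while excess > 0:  # clamping at the minimum can leave a remainder
            i = int(np.argmax(lengths))
            take = min(int(lengths[i]) - config.gene_length_min, excess)
            if take == 0:
                raise ValueError("cannot fit requested genes")
            lengths[i] -= take
            excess -= take
    # distribute the leftover space randomly over the n+1 gaps
    extra = L - int(lengths.sum()) - (n + 1) * gap
    cuts = np.sort(rng.integers(0, extra + 1, size=n))
    gap_extras = np.diff(np.concatenate([[0], cuts, [extra]]))
    strands = rng.choice(["+", "-"], size=n)
    genes: list[GeneModel] = []
    pos = 0
    for i in range(n):
        pos += gap + int(gap_extras[i])
        start = pos + 1
        end = pos + int(lengths[i])
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:04d}",
                replicon=config.replicon,
                start=start,
                end=end,
                strand=str(strands[i]),
                product=f"simulated protein {i + 1}",
            )
        )
        pos = end
    return genome, genes


def _draw_site_sequence(rng: np.random.Generator, mutation_rate: float) -> str:
    letters = list(rng.choice(_BASES, size=SITE_LEN))
    for offset, base in CORE.items():
        if rng.random() < mutation_rate:
            letters[offset] = str(rng.choice([b for b in "ACGT" if b != base]))
        else:
            letters[offset] = base
    return "".join(letters)


def _intergenic_gaps(
    genes: Sequence[GeneModel], length: int
) -> list[tuple[int, int]]:
    """1-based inclusive intervals not covered by any gene."""
    gaps = []
    pos = 1
    for g in sorted(genes, key=lambda g: g.start):
        if g.start > pos:
            gaps.append((pos, g.start - 1))
        pos = max(pos, g.end + 1)
    if pos <= length:
        gaps.append((pos, length))
    return gaps


def plant_sites(
    genome: Genome, genes: Sequence[GeneModel], config: SimulationConfig
) -> tuple[Genome, SyntheticTruth]:
    """Write n_sites degenerate 14-mers into the genome and record the truth.

    A ``frac_intragenic_sites`` share goes inside gene bodies; the rest in
    intergenic gaps. Half of the intergenic sites additionally get canonical
    Class II geometry (TAN3T box at a 22-nt spacer and a TSP 35 nt from the
    site 3' end) written into the sequence and recorded.
    """
    rng = _rng(config, 1)
    name = config.replicon
    L = genome.lengths[name]
    seq = list(genome.replicons[name])
    n_intra = int(round(config.n_sites * config.frac_intragenic_sites))
    n_inter = config.n_sites - n_intra
    gaps = _intergenic_gaps(genes, L)
    # room for the site plus downstream promoter geometry and slack
    geometry_span = SITE_LEN + TSP_OFFSET + 5
    wide_gaps = [g for g in gaps if g[1] - g[0] + 1 >= geometry_span + 10]
    if n_inter > 0 and not wide_gaps:
        raise ValueError("insufficient intergenic space to plant sites")
    genes_with_room = [g for g in genes if g.length >= SITE_LEN + 10]
    if n_intra > 0 and not genes_with_room:
        raise ValueError("no gene bodies long enough to plant sites")

    placed_centers: list[float] = []
    sites: list[SiteRecord] = []
    tsps: list[tuple[str, int, str]] = []
    n_class_ii = n_inter // 2
    max_tries = 200 * max(config.n_sites, 1)
    tries = 0
    while len(sites) < config.n_sites:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place all sites without overlap")
        k = len(sites)
        intragenic = k < n_intra
        class_ii = (not intragenic) and (k - n_intra) < n_class_ii
        strand = str(rng.choice(["+", "-"]))
        if intragenic:
            gene = genes_with_room[rng.integers(len(genes_with_room))]
            start = int(rng.integers(gene.start, gene.end - SITE_LEN + 2))
        else:
            lo, hi = wide_gaps[rng.integers(len(wide_gaps))]
            if strand == "+":
                start = int(rng.integers(lo, hi - geometry_span + 2))
            else:
                start = int(rng.integers(lo + geometry_span - SITE_LEN, hi - SITE_LEN + 2))
        center = start + (SITE_LEN - 1) / 2
        if any(abs(center - c) < MIN_SITE_SPACING for c in placed_centers):
            continue
        oriented = _draw_site_sequence(rng, config.site_mutation_rate)
        genomic = oriented if strand == "+" else revcomp(oriented)
        seq[start - 1 : start - 1 + SITE_LEN] = list(genomic)
        record = SiteRecord(
            site_id=len(sites) + 1,
            replicon=name,
            start=start,
            strand=strand,
            sequence=oriented,
            strength=float(
                np.exp(
                    rng.uniform(
                        np.log(config.strength_min), np.log(config.strength_max)
                    )
                )
            ),
            intragenic=intragenic,
            class_ii=class_ii,
        )
        if class_ii:
            box = "TA" + "".join(rng.choice(_BASES, size=3)) + "T"
            if strand == "+":
                end3 = record.end
                box_start = end3 + BOX_SPACER + 1
                tsp = end3 + TSP_OFFSET
                seq[box_start - 1 : box_start - 1 + BOX_LEN] = list(box)
            else:
                end3 = record.start
                box_start = end3 - BOX_SPACER - BOX_LEN
                tsp = end3 - TSP_OFFSET
                seq[box_start - 1 : box_start - 1 + BOX_LEN] = list(revcomp(box))
            record.box_start = box_start
            record.tsp = tsp
            tsps.append((name, tsp, strand))
        placed_centers.append(center)
        sites.append(record)
    planted = Genome({name: "".join(seq)})
    truth = SyntheticTruth(
        replicon=name,
        genome_length=L,
        sites=sites,
        genes=list(genes),
        tsps=tsps,
    )
    return planted, truth


def _uniform_tags(
    rng: np.random.Generator, rate: float, length: int
) -> np.ndarray:
    n = rng.poisson(rate * length)
    return np.sort(rng.integers(1, length + 1, size=n))


def simulate_tags(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[TagLibrary, TagLibrary]:
    """Fragment-end tag model: ChIP library with site pileups plus uniform
    background, and a uniform matched input library."""
    rng = _rng(config, 2)
    L = truth.genome_length
    name = truth.replicon
    fwd: list[np.ndarray] = []
    rev: list[np.ndarray] = []
    for site in truth.sites:
        n_pairs = rng.poisson(site.strength)
        if n_pairs == 0:
            continue
        frag = np.maximum(rng.normal(config.fragment_mean, config.fragment_sd, n_pairs), 50.0)
        centers = site.center + rng.integers(-10, 11, size=n_pairs)
        left = np.rint(centers - frag / 2).astype(np.int64)
        right = np.rint(centers + frag / 2).astype(np.int64)
        fwd.append(np.clip(left, 1, L))
        rev.append(np.clip(right, 1, L))
    fwd.append(_uniform_tags(rng, config.background_rate, L))
    rev.append(_uniform_tags(rng, config.background_rate, L))
    chip = TagLibrary(
        sample="chip",
        tags={name: (np.concatenate(fwd), np.concatenate(rev))},
        lengths={name: L},
    )
    input_lib = TagLibrary(
        sample="input",
        tags={
            name: (
                _uniform_tags(rng, config.input_rate, L),
                _uniform_tags(rng, config.input_rate, L),
            )
        },
        lengths={name: L},
    )
    return chip, input_lib


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Genome, list[GeneModel], SyntheticTruth, TagLibrary, TagLibrary]:
    """Convenience end-to-end generator: genome, genes, truth, chip, input."""
    genome, genes = generate_genome(config)
    genome, truth = plant_sites(genome, genes, config)
    chip, input_lib = simulate_tags(truth, config)
    return genome, genes, truth, chip, input_lib
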