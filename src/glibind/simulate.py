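"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study-shaped inputs end to end: a random genome,
ChIP coverage tracks with planted enrichment peaks over Poisson background
plus an IgG-like control, planted motif instances, treated/control expression
tables with planted log2 fold changes, and region sets (CTCF, conserved
elements, mouse Gli1/Gli3 in human coordinates) with controlled co-occupancy
fractions. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage import CoverageTrack
from .expression import CONTROL_PREFIX, TREATED_PREFIX, Gene
from .motif import WeightMatrix, reverse_complement
from .regions import Region

import pandas as pd

#: Printed per-fraction peak-intensity distributions (coverage units).
GLI1_INTENSITY = (206.8, 120.6)
GLI2_INTENSITY = (89.0, 62.0)
#: Printed mouse binding-region intensity distributions.
MOUSE_GLI1_INTENSITY = (3.1, 1.4)
MOUSE_GLI3_INTENSITY = (5.4, 2.5)


@dataclass
class SyntheticGenome:
    """A random genome: chromosome name -> A/C/G/T sequence."""

    sequence: dict[str, str]
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, seq in self.sequence.items():
            extra = set(seq) - set("ACGT")
            if extra:
                raise ValueError(f"{chrom}: non-ACGT characters {sorted(extra)}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequence)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequence.items()}


@dataclass(frozen=True)
class TruthPeak:
    chrom: str
    center: int
    intensity: float
    fraction: str

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("planted intensity must be positive")


@dataclass(frozen=True)
class PlantedMotif:
    chrom: str
    position: int
    strand: str
    motif: str


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests, JSON round-trippable."""

    planted_peaks: list[TruthPeak] = field(default_factory=list)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    deg_truth: dict[str, float] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)
    conserved_elements: list[Region] = field(default_factory=list)
    mouse_regions: dict[str, list[Region]] = field(default_factory=dict)
    ctcf_regions: list[Region] = field(default_factory=list)

    def to_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=encode, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        raw = json.loads(text)
        return cls(
            planted_peaks=[TruthPeak(**p) for p in raw["planted_peaks"]],
            planted_motifs=[PlantedMotif(**m) for m in raw["planted_motifs"]],
            deg_truth=raw["deg_truth"],
            gene_classes=raw["gene_classes"],
            conserved_elements=[Region(**r) for r in raw["conserved_elements"]],
            mouse_regions={
                k: [Region(**r) for r in v] for k, v in raw["mouse_regions"].items()
            },
            ctcf_regions=[Region(**r) for r in raw["ctcf_regions"]],
        )


def generate_genome(
    lengths: Mapping[str, int], gc_fraction: float = 0.41, seed: int = 0
) -> SyntheticGenome:
    """I.i.d. random genome with the stated GC fraction (A/T and C/G split
    evenly). Deterministic under the seed."""
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    sequence = {}
    for chrom, length in lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome length must be positive, got {length} for {chrom}")
        draws = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
        sequence[chrom] = draws.tobytes().decode()
    return SyntheticGenome(sequence=sequence, seed=seed)


def plant_motif_at(
    genome: SyntheticGenome, chrom: str, position: int, strand: str, matrix: WeightMatrix
) -> SyntheticGenome:
    """Write the matrix consensus (or its reverse complement on '-') into the
    sequence at ``position``. Returns a new genome."""
    word = matrix.consensus if strand == "+" else reverse_complement(matrix.consensus)
    seq = genome.sequence[chrom]
    if position < 0 or position + len(word) > len(seq):
        raise ValueError(f"motif at {chrom}:{position} falls off the chromosome")
    sequence = dict(genome.sequence)
    sequence[chrom] = seq[:position] + word + seq[position + len(word) :]
    return SyntheticGenome(sequence=sequence, seed=genome.seed)


def plant_motifs(
    genome: SyntheticGenome,
    matrix: WeightMatrix,
    n: int,
    seed: int = 0,
    chrom: str | None = None,
    max_tries_per_instance: int = 1000,
) -> tuple[SyntheticGenome, list[PlantedMotif]]:
    """Plant ``n`` non-overlapping consensus instances at random positions
    with uniformly random strand; positions are recorded as truth. Raises
    RuntimeError if placement fails after bounded retries."""
    if n == 0:
        return genome, []
    chrom = chrom or genome.chrom_names[0]
    length = genome.chrom_lengths[chrom]
    L = matrix.length
    if n * L >= length:
        raise ValueError("motifs cannot fit in the chromosome")
    rng = np.random.default_rng(seed)
    taken: list[tuple[int, int]] = []
    planted: list[PlantedMotif] = []
    out = genome
    for _ in range(n):
        for _attempt in range(max_tries_per_instance):
            pos = int(rng.integers(0, length - L + 1))
            if all(pos + L <= s or pos >= e for s, e in taken):
                break
        else:
            raise RuntimeError(f"could not place {n} non-overlapping motifs")
        strand = "+" if rng.random() < 0.5 else "-"
        out = plant_motif_at(out, chrom, pos, strand, matrix)
        taken.append((pos, pos + L))
        planted.append(PlantedMotif(chrom=chrom, position=pos, strand=strand, motif=matrix.name))
    planted.sort(key=lambda m: (m.chrom, m.position))
    return out, planted


def peak_profile(frag_len: int = 250, plateau_frac: float = 0.1) -> np.ndarray:
    """Unit-height flat-top triangular bump of total width ``frag_len``: a
    central plateau of half-width plateau_frac*frag_len/2 with linear ramps
    to zero at +/- frag_len/2. The narrow plateau (half-width 12.5 bp at the
    250-bp default) keeps the noise-free apex within frag_len/20 of the peak
    center and the summit unambiguous under Poisson noise."""
    half = frag_len / 2.0
    plateau = plateau_frac * half
    offsets = np.arange(-int(half), int(half) + 1)
    shape = np.clip((half - np.abs(offsets)) / (half - plateau), 0.0, 1.0)
    return shape


def simulate_chip_coverage(
    genome: SyntheticGenome,
    peaks: Sequence[TruthPeak],
    library_size: int = 1_000_000,
    frag_len: int = 250,
    noise_rate: float = 0.1,
    seed: int = 0,
) -> CoverageTrack:
    """Per-base coverage: homogeneous Poisson background at ``noise_rate``
    reads/bp plus, per planted peak, a flat-top triangular bump of width
    ~frag_len centered on the peak with apex height equal to the planted
    intensity."""
    if frag_len <= 0:
        raise ValueError("frag_len must be positive")
    if noise_rate < 0:
        raise ValueError("noise_rate must be non-negative")
    rng = np.random.default_rng(seed)
    shape = peak_profile(frag_len)
    half = len(shape) // 2
    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths.items():
        base = (
            rng.poisson(noise_rate, size=length).astype(float)
            if noise_rate > 0
            else np.zeros(length)
        )
        values[chrom] = base
    for peak in peaks:
        arr = values[peak.chrom]
        lo = peak.center - half
        hi = lo + len(shape)
        s_lo, s_hi = max(0, -lo), len(shape) - max(0, hi - len(arr))
        arr[max(0, lo) : min(len(arr), hi)] += peak.intensity * shape[s_lo:s_hi]
    return CoverageTrack(values=values, library_size=library_size)


def simulate_expression(
    genes: Sequence[Gene],
    deg_truth: Mapping[str, float],
    n_per_group: int = 4,
    noise_sd: float = 0.25,
    baseline: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Log2-scale expression table: control replicates ~ Normal(baseline,
    noise_sd), treated ~ Normal(baseline + planted log2FC, noise_sd)."""
    if n_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        lfc = float(deg_truth.get(gene.gene_id, 0.0))
        ctrl = rng.normal(baseline, noise_sd, size=n_per_group)
        trt = rng.normal(baseline + lfc, noise_sd, size=n_per_group)
        row = {
            "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "start": gene.start,
            "end": gene.end,
            "strand": gene.strand,
        }
        row.update({f"{CONTROL_PREFIX}{i + 1}": v for i, v in enumerate(ctrl)})
        row.update({f"{TREATED_PREFIX}{i + 1}": v for i, v in enumerate(trt)})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_region_sets(
    reference: Sequence,
    n_regions: int,
    cooccupancy_fraction: float,
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    d: int = 250,
    width: int = 200,
    label: str = "",
    intensity: tuple[float, float] | None = None,
) -> tuple[list[Region], list[bool]]:
    """Generate ``n_regions`` intervals of which a known fraction lies within
    ``d`` bp of the reference set; truth co-occupancy flags are returned per
    interval. Optional intensities are drawn Normal(mean, sd)."""
    if not 0 <= cooccupancy_fraction <= 1:
        raise ValueError("cooccupancy_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reference = list(reference)
    if cooccupancy_fraction > 0 and not reference:
        raise ValueError("cannot plant co-occupancy without a reference set")
    n_near = int(round(n_regions * cooccupancy_fraction))
    flags = [True] * n_near + [False] * (n_regions - n_near)
    rng.shuffle(flags)
    chroms = sorted(chrom_lengths)
    regions: list[Region] = []
    # pair co-occupied regions with distinct references (cycle only when the
    # reference set is exhausted) so each planted pair forms its own cluster
    ref_order = rng.permutation(len(reference)) if reference else np.zeros(0, int)
    n_placed_near = 0
    for i, near in enumerate(flags):
        if near:
            ref = reference[int(ref_order[n_placed_near % len(reference)])]
            n_placed_near += 1
            gap = int(rng.integers(0, d + 1))
            if rng.random() < 0.5:
                start = ref.end + gap
            else:
                start = ref.start - gap - width
            start = max(0, min(start, chrom_lengths[ref.chrom] - width))
            chrom = ref.chrom
        else:
            for _try in range(10_000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, chrom_lengths[chrom] - width))
                gap_ok = all(
                    r.chrom != chrom or start > r.end + d or start + width < r.start - d
                    for r in reference
                )
                if gap_ok:
                    break
            else:
                raise RuntimeError("could not place a non-co-occupied region")
        score = float(rng.normal(*intensity)) if intensity else None
        regions.append(
            Region(chrom=chrom, start=start, end=start + width,
                   name=f"{label}_{i}" if label else str(i), score=score)
        )
    order = sorted(range(len(regions)), key=lambda j: (regions[j].chrom, regions[j].start))
    return [regions[j] for j in order], [flags[j] for j in order]


# ---------------------------------------------------------------------------
# Whole-study generator
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Defaults for the bundled synthetic study.

    One 50-kb chromosome is divided into 1-kb gene blocks, one gene per
    block. Planted binding loci sit inside gene bodies so each gene's
    regulatory neighborhood contains exactly its own loci. 50 peak records
    are planted: 14 GLI1-only, 24 GLI2-only, and 6 co-occupied pairs (12
    records), giving a planted co-occupancy of 6/20 = 0.30 in the GLI1
    fraction. Gli-consensus motifs are planted at 21 of the 50 peak centers
    (3 of the 6 co-occupied loci and 15 single loci): presence 21/50 = 0.42.
    Intensities follow the printed per-fraction Normal parameters truncated
    below at 60 coverage units so every planted peak clears the auto
    background threshold (SNR >= 100 at the default noise rate).
    """

    chrom: str = "chr1"
    block: int = 1000
    n_blocks: int = 50
    gene_body: int = 400
    n_g1_only: int = 14
    n_g2_only: int = 24
    n_gis: int = 6
    gis_offset: int = 60
    intensity_floor: float = 60.0
    noise_rate: float = 0.5
    frag_len: int = 250
    library_size: int = 1_000_000
    gc_fraction: float = 0.41
    gli_consensus: str = "GACCACCCA"
    ctcf_consensus: str = "CCMMYYCHHGGTGG"
    n_motif_gis_loci: int = 3
    n_motif_single_loci: int = 15
    ctcf_n: int = 60
    ctcf_cooccupancy: float = 0.5
    ctcf_motif_fraction: float = 0.7
    conserved_width: int = 300
    n_conserved_decoys: int = 20
    mouse_g1_n: int = 30
    mouse_g3_n: int = 80
    mouse_cooccupancy: float = 0.4
    mouse_width: int = 200
    n_per_group: int = 4
    noise_sd: float = 0.25
    baseline: float = 8.0
    deg_effect: float = 2.0
    # planted DEG mix: (class, n_up, n_down)
    deg_plan: tuple = (("G1", 6, 2), ("G2", 2, 3), ("GIS", 2, 1), ("none", 2, 0))


@dataclass
class StudyInputs:
    """Everything the pipeline consumes, plus ground truth."""

    genome: SyntheticGenome
    g1_track: CoverageTrack
    g2_track: CoverageTrack
    control_track: CoverageTrack
    genes: list[Gene]
    expression: pd.DataFrame
    truth: TruthSet
    gli_matrix: WeightMatrix
    ctcf_matrix: WeightMatrix


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    while True:
        x = rng.normal(mean, sd)
        if x >= floor:
            return float(x)


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyInputs:
    """Generate the full synthetic study deterministically from one seed."""
    from .motif import matrix_from_iupac  # local to avoid import cycles at module load

    cfg = config or StudyConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(10)]
    rng = np.random.default_rng(seeds[0])

    chrom = cfg.chrom
    length = cfg.block * cfg.n_blocks
    genome = generate_genome({chrom: length}, gc_fraction=cfg.gc_fraction, seed=seeds[1])
    gli_matrix = matrix_from_iupac(cfg.gli_consensus, name="GLI")
    ctcf_matrix = matrix_from_iupac(cfg.ctcf_consensus, name="CTCF")

    # gene layout: one gene per block, body centered in the block
    genes: list[Gene] = []
    centers: list[int] = []
    for i in range(cfg.n_blocks):
        c = i * cfg.block + cfg.block // 2
        half_body = cfg.gene_body // 2
        genes.append(
            Gene(
                gene_id=f"gene_{i:03d}",
                chrom=chrom,
                start=c - half_body,
                end=c + half_body,
                strand="+" if i % 2 == 0 else "-",
            )
        )
        centers.append(c)

    # assign binding classes to blocks
    n_loci = cfg.n_g1_only + cfg.n_g2_only + cfg.n_gis
    if n_loci > cfg.n_blocks:
        raise ValueError("more binding loci than gene blocks")
    class_list = (
        ["G1"] * cfg.n_g1_only + ["G2"] * cfg.n_g2_only + ["GIS"] * cfg.n_gis
    ) + ["none"] * (cfg.n_blocks - n_loci)
    rng.shuffle(class_list)
    gene_classes = {genes[i].gene_id: cls for i, cls in enumerate(class_list)}

    # planted peaks per class
    planted: list[TruthPeak] = []
    locus_centers: dict[int, str] = {}  # block index -> class
    for i, cls in enumerate(class_list):
        c = centers[i]
        if cls == "G1":
            planted.append(
                TruthPeak(chrom, c, _truncated_normal(rng, *GLI1_INTENSITY, cfg.intensity_floor), "GLI1")
            )
            locus_centers[i] = cls
        elif cls == "G2":
            planted.append(
                TruthPeak(chrom, c, _truncated_normal(rng, *GLI2_INTENSITY, cfg.intensity_floor), "GLI2")
            )
            locus_centers[i] = cls
        elif cls == "GIS":
            planted.append(
                TruthPeak(chrom, c - cfg.gis_offset,
                          _truncated_normal(rng, *GLI1_INTENSITY, cfg.intensity_floor), "GLI1")
            )
            planted.append(
                TruthPeak(chrom, c + cfg.gis_offset,
                          _truncated_normal(rng, *GLI2_INTENSITY, cfg.intensity_floor), "GLI2")
            )
            locus_centers[i] = cls

    # plant Gli motifs at locus centers: a fixed number of co-occupied loci
    # and of single-fraction loci, so the truth-window presence fraction is
    # exactly (2*n_motif_gis_loci + n_motif_single_loci) / n_peak_records
    gis_blocks = [i for i, cls in locus_centers.items() if cls == "GIS"]
    single_blocks = [i for i, cls in locus_centers.items() if cls in ("G1", "G2")]
    rng.shuffle(gis_blocks)
    rng.shuffle(single_blocks)
    motif_blocks = gis_blocks[: cfg.n_motif_gis_loci] + single_blocks[: cfg.n_motif_single_loci]
    planted_motifs: list[PlantedMotif] = []
    for i in sorted(motif_blocks):
        pos = centers[i] - gli_matrix.length // 2
        strand = "+" if rng.random() < 0.5 else "-"
        genome = plant_motif_at(genome, chrom, pos, strand, gli_matrix)
        planted_motifs.append(PlantedMotif(chrom, pos, strand, gli_matrix.name))

    # coverage tracks
    g1_truth = [p for p in planted if p.fraction == "GLI1"]
    g2_truth = [p for p in planted if p.fraction == "GLI2"]
    g1_track = simulate_chip_coverage(
        genome, g1_truth, cfg.library_size, cfg.frag_len, cfg.noise_rate, seed=seeds[2]
    )
    g2_track = simulate_chip_coverage(
        genome, g2_truth, cfg.library_size, cfg.frag_len, cfg.noise_rate, seed=seeds[3]
    )
    control_track = simulate_chip_coverage(
        genome, [], cfg.library_size, cfg.frag_len, cfg.noise_rate, seed=seeds[4]
    )

    # conserved elements: one per binding locus (so selection criterion b
    # keeps all true loci) plus random decoys
    conserved = [
        Region(chrom, centers[i] - cfg.conserved_width // 2,
               centers[i] + cfg.conserved_width // 2, name=f"cons_{i}")
        for i in sorted(locus_centers)
    ]
    locus_regions = list(conserved)
    decoys, _ = generate_region_sets(
        [], cfg.n_conserved_decoys, 0.0, genome.chrom_lengths, seed=seeds[5],
        width=cfg.conserved_width, label="cons_decoy",
    )
    conserved = sorted(conserved + decoys, key=lambda r: (r.chrom, r.start))

    # CTCF regions with a controlled co-occupancy fraction vs the true loci
    ctcf, _ctcf_flags = generate_region_sets(
        locus_regions, cfg.ctcf_n, cfg.ctcf_cooccupancy, genome.chrom_lengths,
        seed=seeds[6], width=cfg.mouse_width, label="CTCF",
    )
    # plant CTCF consensus motifs inside a fraction of the CTCF regions
    n_ctcf_motif = int(round(cfg.ctcf_motif_fraction * len(ctcf)))
    for region in ctcf[:n_ctcf_motif]:
        pos = (region.start + region.end) // 2 - ctcf_matrix.length // 2
        if 0 <= pos and pos + ctcf_matrix.length <= length:
            genome = plant_motif_at(genome, chrom, pos, "+", ctcf_matrix)
            planted_motifs.append(PlantedMotif(chrom, pos, "+", ctcf_matrix.name))

    # mouse binding-region sets (already in human coordinates)
    mouse_g1, _ = generate_region_sets(
        locus_regions, cfg.mouse_g1_n, cfg.mouse_cooccupancy, genome.chrom_lengths,
        seed=seeds[7], width=cfg.mouse_width, label="mG1",
        intensity=MOUSE_GLI1_INTENSITY,
    )
    mouse_g3, _ = generate_region_sets(
        locus_regions, cfg.mouse_g3_n, cfg.mouse_cooccupancy, genome.chrom_lengths,
        seed=seeds[8], width=cfg.mouse_width, label="mG3",
        intensity=MOUSE_GLI3_INTENSITY,
    )
    # planted mouse intensities must be positive (truth invariant)
    mouse_g1 = [dataclasses.replace(r, score=max(r.score, 0.05)) for r in mouse_g1]
    mouse_g3 = [dataclasses.replace(r, score=max(r.score, 0.05)) for r in mouse_g3]

    # expression with planted effects on genes of known binding class
    deg_truth: dict[str, float] = {}
    for cls, n_up, n_down in cfg.deg_plan:
        members = [g.gene_id for g in genes if gene_classes[g.gene_id] == cls]
        chosen = list(members)
        rng.shuffle(chosen)
        for gid in chosen[:n_up]:
            deg_truth[gid] = cfg.deg_effect
        for gid in chosen[n_up : n_up + n_down]:
            deg_truth[gid] = -cfg.deg_effect
    expression = simulate_expression(
        genes, deg_truth, cfg.n_per_group, cfg.noise_sd, cfg.baseline, seed=seeds[9]
    )

    truth = TruthSet(
        planted_peaks=sorted(planted, key=lambda p: (p.chrom, p.center, p.fraction)),
        planted_motifs=sorted(planted_motifs, key=lambda m: (m.chrom, m.position)),
        deg_truth=deg_truth,
        gene_classes=gene_classes,
        conserved_elements=conserved,
        mouse_regions={"mG1": mouse_g1, "mG3": mouse_g3},
        ctcf_regions=ctcf,
    )
    return StudyInputs(
        genome=genome,
        g1_track=g1_track,
        g2_track=g2_track,
        control_track=control_track,
        genes=genes,
        expression=expression,
        truth=truth,
        gli_matrix=gli_matrix,
        ctcf_matrix=ctcf_matrix,
    )
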