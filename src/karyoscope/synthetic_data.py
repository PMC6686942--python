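"""Synthetic genomes with a planted X chromosome and a planted fusion.

This module generates the ground-truth inputs the downstream analyses
assume, at toy scale, so the whole pipeline is testable without any
sequencing data:

* a multi-scaffold genome in which one scaffold is the X (present at a
  single copy in XO males, two copies in XX females),
* GC and repeat content structured as chromosome *arms vs center* —
  nematode autosome arms are repeat- and recombination-rich relative to
  their centers, and the generator plants that contrast,
* genes placed uniformly, with a few planted tandem gene-family clusters
  (the pattern produced by local gene-family expansions),
* a reference karyotype related to the focal genome through a
  :class:`FusionMap`: by default the focal X descends from a fusion of
  reference chromosomes II and IV with segment lengths in ratio 10 : 7.5,
* female (XX) and male (XO) single-end read placements at configurable
  depth, with Poisson-distributed per-scaffold read counts.

Everything is deterministic given ``(specs, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import io as kio

__all__ = [
    "ScaffoldSpec",
    "GenomeModel",
    "ReadPlacementSet",
    "OrthologPair",
    "FusionMap",
    "default_scaffold_specs",
    "default_fusion_map",
    "simulate_genome",
    "simulate_reads",
    "simulate_orthologs",
    "write_fixture_bundle",
    "read_truth",
    "orthologs_to_frame",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ScaffoldSpec:
    """Declarative description of one synthetic scaffold.

    ``arm_fraction`` is the portion of *each* end treated as an "arm";
    arms use ``gc_arms`` / ``repeat_rate_arms``, the remainder uses the
    center parameters. Repeat rates are expected repeat intervals per
    100 kb (a Poisson intensity).
    """

    name: str
    length: int
    is_x: bool = False
    gc_center: float = 0.45
    gc_arms: float = 0.45
    arm_fraction: float = 0.25
    repeat_rate_center: float = 5.0
    repeat_rate_arms: float = 20.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"scaffold {self.name!r}: length must be > 0, got {self.length}")
        for attr in ("gc_center", "gc_arms"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"scaffold {self.name!r}: {attr}={v} outside [0, 1]")
        if not 0.0 <= self.arm_fraction <= 0.5:
            raise ValueError(
                f"scaffold {self.name!r}: arm_fraction={self.arm_fraction} outside [0, 0.5]"
            )
        for attr in ("repeat_rate_center", "repeat_rate_arms"):
            v = getattr(self, attr)
            if v < 0:
                raise ValueError(f"scaffold {self.name!r}: {attr}={v} must be >= 0")


@dataclass(frozen=True)
class FusionMap:
    """Which reference chromosome each focal-genome segment descends from.

    ``assignments`` rows are ``(focal_scaffold, (start, end), ref_chromosome)``
    with 0-based half-open intervals, non-overlapping within a scaffold.
    Positions covered by no interval have reference label ``"none"``.
    """

    assignments: tuple[tuple[str, tuple[int, int], str], ...]

    def __post_init__(self) -> None:
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for scaffold, (start, end), _ in self.assignments:
            if not 0 <= start < end:
                raise ValueError(f"bad fusion interval [{start}, {end}) on {scaffold!r}")
            by_scaffold.setdefault(scaffold, []).append((start, end))
        for scaffold, ivals in by_scaffold.items():
            ivals.sort()
            for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping fusion intervals on {scaffold!r}")

    def label_at(self, scaffold: str, pos: int) -> str:
        for name, (start, end), label in self.assignments:
            if name == scaffold and start <= pos < end:
                return label
        return "none"

    def segments_of(self, scaffold: str) -> list[tuple[int, int, str]]:
        segs = [
            (start, end, label)
            for name, (start, end), label in self.assignments
            if name == scaffold
        ]
        return sorted(segs)


@dataclass
class GenomeModel:
    """A generated genome plus its planted ground truth.

    ``genes`` rows are ``(scaffold, start, end, strand, gene_id, family)``;
    ``repeats`` rows are ``(scaffold, start, end)``. ``truth_x`` holds the
    scaffolds simulated at single copy in males; ``truth_clusters`` the
    planted tandem gene clusters ``(scaffold, start, end, family)``.
    """

    specs: tuple[ScaffoldSpec, ...]
    sequences: dict[str, str]
    genes: list[tuple]
    repeats: list[tuple[str, int, int]]
    truth_x: set[str]
    truth_clusters: list[tuple[str, int, int, str]] = field(default_factory=list)
    seed: int | None = None

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {s.name: s.length for s in self.specs}

    def spec_of(self, name: str) -> ScaffoldSpec:
        return next(s for s in self.specs if s.name == name)


@dataclass
class ReadPlacementSet:
    """Single-end fixed-length read placements for one sample.

    Placements are stored per scaffold as sorted arrays of 0-based start
    positions; ``placements()`` iterates ``(scaffold, start, read_length)``
    tuples.
    """

    sample_sex: str
    read_length: int
    starts: dict[str, np.ndarray]
    seed: int

    @property
    def total_reads(self) -> int:
        return int(sum(len(v) for v in self.starts.values()))

    def placements(self) -> Iterator[tuple[str, int, int]]:
        for scaffold, arr in self.starts.items():
            for s in arr:
                yield scaffold, int(s), self.read_length


@dataclass(frozen=True)
class OrthologPair:
    """One-to-one ortholog between a focal gene and a reference gene."""

    focal_gene_id: str
    focal_scaffold: str
    focal_position: int
    ref_gene_id: str
    ref_chromosome: str


# ---------------------------------------------------------------------------
# Default toy configuration

def default_scaffold_specs() -> list[ScaffoldSpec]:
    """The default five-scaffold toy genome with one planted X.

    The X is the largest scaffold (as in real nematode assemblies where
    the X often assembles as the largest, most contiguous piece) and is
    sized so the planted fusion breakpoint at 4/7 of its length (segment
    ratio 10 : 7.5) lands on a 500-kb painting-window boundary.
    """
    return [
        ScaffoldSpec("scaffold_0", 3_500_000, is_x=True, gc_center=0.42,
                     gc_arms=0.50, arm_fraction=0.25,
                     repeat_rate_center=5.0, repeat_rate_arms=25.0),
        ScaffoldSpec("scaffold_1", 2_000_000, gc_center=0.44, gc_arms=0.48,
                     repeat_rate_center=6.0, repeat_rate_arms=18.0),
        ScaffoldSpec("scaffold_2", 1_500_000, gc_center=0.45, gc_arms=0.47,
                     repeat_rate_center=6.0, repeat_rate_arms=18.0),
        ScaffoldSpec("scaffold_3", 1_000_000, gc_center=0.46, gc_arms=0.48,
                     repeat_rate_center=7.0, repeat_rate_arms=16.0),
        ScaffoldSpec("scaffold_4", 600_000, gc_center=0.46, gc_arms=0.48,
                     repeat_rate_center=7.0, repeat_rate_arms=16.0),
    ]


def default_fusion_map(specs: Sequence[ScaffoldSpec] | None = None) -> FusionMap:
    """Reference-karyotype map planting a II+IV fusion on the X scaffold.

    The X scaffold descends from reference chromosome II over its first
    4/7 (the 10 : 7.5 segment ratio) and chromosome IV over the rest;
    each autosome descends wholly from a single reference chromosome.
    """
    if specs is None:
        specs = default_scaffold_specs()
    autosome_labels = ["I", "III", "V", "X"]
    assignments: list[tuple[str, tuple[int, int], str]] = []
    i = 0
    for spec in specs:
        if spec.is_x:
            breakpoint_ = round(spec.length * 4 / 7)
            assignments.append((spec.name, (0, breakpoint_), "II"))
            assignments.append((spec.name, (breakpoint_, spec.length), "IV"))
        else:
            assignments.append((spec.name, (0, spec.length), autosome_labels[i % 4]))
            i += 1
    return FusionMap(tuple(assignments))


# ---------------------------------------------------------------------------
# Genome simulation

def _simulate_sequence(spec: ScaffoldSpec, rng: np.random.Generator) -> str:
    """Draw a sequence base-by-base with region-specific GC probability."""
    arm = int(spec.arm_fraction * spec.length)
    p_gc = np.full(spec.length, spec.gc_center)
    if arm:
        p_gc[:arm] = spec.gc_arms
        p_gc[spec.length - arm:] = spec.gc_arms
    is_gc = rng.random(spec.length) < p_gc
    second = rng.random(spec.length) < 0.5  # C-vs-G / T-vs-A, equiprobable
    codes = np.where(is_gc, np.where(second, 2, 1), np.where(second, 3, 0))
    return _BASES[codes].tobytes().decode("ascii")


def _region_bounds(spec: ScaffoldSpec) -> list[tuple[int, int, bool]]:
    """(start, end, is_arm) partition of a scaffold."""
    arm = int(spec.arm_fraction * spec.length)
    if arm == 0:
        return [(0, spec.length, False)]
    return [
        (0, arm, True),
        (arm, spec.length - arm, False),
        (spec.length - arm, spec.length, True),
    ]


def simulate_genome(
    specs: Sequence[ScaffoldSpec],
    seed: int,
    genes_per_mb: float = 350.0,
    gene_length_range: tuple[int, int] = (500, 3000),
    repeat_length_range: tuple[int, int] = (100, 1000),
    tandem_clusters: int = 2,
    tandem_cluster_size: int = 5,
    tandem_gap: int = 1500,
    with_sequence: bool = True,
) -> GenomeModel:
    """Generate a toy genome with planted X, arm structure, and gene clusters.

    Sequences are drawn base-by-base with per-position GC probability
    ``gc_arms`` inside the first/last ``arm_fraction`` of each scaffold and
    ``gc_center`` elsewhere. Repeat intervals follow a Poisson process with
    the region-specific per-100-kb rate. Genes are placed uniformly at
    ``genes_per_mb`` (Poisson counts); additionally ``tandem_clusters``
    runs of ``tandem_cluster_size`` same-family genes with inter-gene gaps
    ≤ ``tandem_gap`` are planted at random positions and recorded in
    ``truth_clusters``.

    The same ``(specs, seed)`` always yields an identical genome.
    ``with_sequence=False`` skips sequence generation (annotations and
    lengths only), for analyses that never touch bases.
    """
    if not specs:
        raise ValueError("specs is empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate scaffold names")
    rng = np.random.default_rng(seed)

    sequences: dict[str, str] = {}
    repeats: list[tuple[str, int, int]] = []
    genes: list[tuple] = []
    truth_clusters: list[tuple[str, int, int, str]] = []
    gene_counter = 0

    for spec in specs:
        if with_sequence:
            sequences[spec.name] = _simulate_sequence(spec, rng)
        # repeats: Poisson process per arm/center region
        for start, end, is_arm in _region_bounds(spec):
            rate = spec.repeat_rate_arms if is_arm else spec.repeat_rate_center
            n = rng.poisson(rate * (end - start) / 100_000)
            if n == 0:
                continue
            pos = np.sort(rng.integers(start, end, size=n))
            lens = rng.integers(*repeat_length_range, size=n, endpoint=True)
            for p, ln in zip(pos, lens):
                repeats.append((spec.name, int(p), int(min(p + ln, spec.length))))
        # genes: uniform placement
        n_genes = rng.poisson(genes_per_mb * spec.length / 1e6)
        lo, hi = gene_length_range
        hi = min(hi, spec.length)
        lens = rng.integers(lo, hi, size=n_genes, endpoint=True) if n_genes else []
        starts = (
            rng.integers(0, np.maximum(spec.length - np.asarray(lens), 1))
            if n_genes
            else []
        )
        strands = rng.choice(["+", "-"], size=n_genes)
        for s, ln, st in zip(starts, lens, strands):
            genes.append(
                (spec.name, int(s), int(s + ln), str(st), f"gene_{gene_counter:05d}", ".")
            )
            gene_counter += 1

    # planted tandem clusters of a shared gene family
    lengths = {s.name: s.length for s in specs}
    for k in range(tandem_clusters):
        family = f"fam{k}"
        scaffold = names[int(rng.integers(0, len(names)))]
        member_len = 1000
        span = tandem_cluster_size * member_len + (tandem_cluster_size - 1) * tandem_gap
        if span >= lengths[scaffold]:
            continue
        anchor = int(rng.integers(0, lengths[scaffold] - span))
        pos = anchor
        first = pos
        for _ in range(tandem_cluster_size):
            genes.append(
                (scaffold, pos, pos + member_len, "+", f"gene_{gene_counter:05d}", family)
            )
            gene_counter += 1
            pos += member_len + tandem_gap
        truth_clusters.append((scaffold, first, pos - tandem_gap, family))

    genes.sort(key=lambda g: (names.index(g[0]), g[1]))
    return GenomeModel(
        specs=tuple(specs),
        sequences=sequences,
        genes=genes,
        repeats=sorted(repeats, key=lambda r: (names.index(r[0]), r[1])),
        truth_x={s.name for s in specs if s.is_x},
        truth_clusters=truth_clusters,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Read simulation

def simulate_reads(
    genome: GenomeModel,
    sample_sex: str,
    mean_depth: float = 20.0,
    read_length: int = 100,
    seed: int = 0,
) -> ReadPlacementSet:
    """Place single-end reads uniformly, at sex-dependent copy number.

    Expected read count per scaffold is
    ``copy_number * mean_depth * length / (2 * read_length)``, with
    copy number 2 for autosomes in both sexes and for the X in females,
    and 1 for the X in XO males; realized counts are Poisson. At copy
    number 2 this yields per-base depth ``mean_depth``; the male X runs
    at half that — the signal the sex scan detects.
    """
    if sample_sex not in ("female", "male"):
        raise ValueError(f"unknown sample_sex {sample_sex!r} (expected 'female' or 'male')")
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be > 0, got {mean_depth}")
    shortest = min(s.length for s in genome.specs)
    if not 1 <= read_length <= shortest:
        raise ValueError(
            f"read_length {read_length} outside [1, shortest scaffold {shortest}]"
        )
    rng = np.random.default_rng(seed)
    starts: dict[str, np.ndarray] = {}
    for spec in genome.specs:
        copy_number = 1 if (spec.is_x and sample_sex == "male") else 2
        lam = copy_number * mean_depth * spec.length / (2 * read_length)
        n = rng.poisson(lam)
        starts[spec.name] = np.sort(
            rng.integers(0, spec.length - read_length + 1, size=n)
        )
    return ReadPlacementSet(
        sample_sex=sample_sex, read_length=read_length, starts=starts, seed=seed
    )


# ---------------------------------------------------------------------------
# Ortholog simulation

def simulate_orthologs(
    genome: GenomeModel,
    fusion_map: FusionMap,
    n_per_mb: float = 80.0,
    dropout: float = 0.1,
    seed: int = 0,
) -> list[OrthologPair]:
    """Draw one-to-one ortholog pairs whose reference chromosome follows the fusion map.

    Ortholog positions are uniform within each focal scaffold (Poisson
    counts at ``n_per_mb``); each pair's reference chromosome is the
    fusion-map assignment at its position (label ``"none"`` where the map
    is silent). A ``dropout`` fraction of pairs is then removed at random,
    emulating orthologs lost to annotation or one-to-many filtering. Gene
    ids are unique on both sides, so the one-to-one invariant holds by
    construction.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError(f"dropout must be in [0, 1), got {dropout}")
    if n_per_mb <= 0:
        raise ValueError(f"n_per_mb must be > 0, got {n_per_mb}")
    rng = np.random.default_rng(seed)
    pairs: list[OrthologPair] = []
    i = 0
    for spec in genome.specs:
        n = rng.poisson(n_per_mb * spec.length / 1e6)
        positions = np.sort(rng.integers(0, spec.length, size=n))
        for pos in positions:
            pairs.append(
                OrthologPair(
                    focal_gene_id=f"Sc_g{i:06d}",
                    focal_scaffold=spec.name,
                    focal_position=int(pos),
                    ref_gene_id=f"Ce_g{i:06d}",
                    ref_chromosome=fusion_map.label_at(spec.name, int(pos)),
                )
            )
            i += 1
    if dropout > 0 and pairs:
        keep = rng.random(len(pairs)) >= dropout
        pairs = [p for p, k in zip(pairs, keep) if k]
    return pairs


def orthologs_to_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "focal_gene": [p.focal_gene_id for p in pairs],
            "focal_scaffold": [p.focal_scaffold for p in pairs],
            "focal_start": [p.focal_position for p in pairs],
            "ref_gene": [p.ref_gene_id for p in pairs],
            "ref_chromosome": [p.ref_chromosome for p in pairs],
        }
    )


# ---------------------------------------------------------------------------
# Fixture bundle

def write_fixture_bundle(
    genome: GenomeModel,
    reads_f: ReadPlacementSet,
    reads_m: ReadPlacementSet,
    orthologs: Sequence[OrthologPair],
    out_dir: str | Path,
    fusion_map: FusionMap | None = None,
) -> dict[str, Path]:
    """Write the full simulated data set as standard-format files.

    Emits genome FASTA, gene GFF3, repeat BED, one SAM per sample,
    ortholog TSV and a ground-truth TSV (planted X, fusion segments,
    planted clusters). Every file round-trips through this package's own
    readers. Returns ``{kind: path}``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc

    lengths = genome.scaffold_lengths
    paths = {
        "fasta": out / "genome.fasta",
        "genes": out / "genes.gff3",
        "repeats": out / "repeats.bed",
        "reads_female": out / "female.sam",
        "reads_male": out / "male.sam",
        "orthologs": out / "orthologs.tsv",
        "truth": out / "truth.tsv",
    }
    if genome.sequences:
        kio.write_fasta(genome.sequences, paths["fasta"])
    else:
        del paths["fasta"]
    kio.write_gff3(genome.genes, paths["genes"])
    kio.write_bed3(genome.repeats, paths["repeats"])
    kio.write_sam(reads_f.starts, lengths, reads_f.read_length, paths["reads_female"], sample="female")
    kio.write_sam(reads_m.starts, lengths, reads_m.read_length, paths["reads_male"], sample="male")
    orthologs_to_frame(orthologs).to_csv(paths["orthologs"], sep="\t", index=False)

    rows = [("scaffold_length", name, 0, length, "") for name, length in lengths.items()]
    rows += [("x_scaffold", name, 0, lengths[name], "") for name in sorted(genome.truth_x)]
    if fusion_map is not None:
        rows += [
            ("fusion_segment", scaffold, start, end, label)
            for scaffold, (start, end), label in fusion_map.assignments
        ]
    rows += [
        ("tandem_cluster", scaffold, start, end, family)
        for scaffold, start, end, family in genome.truth_clusters
    ]
    pd.DataFrame(rows, columns=["record", "scaffold", "start", "end", "label"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


def read_truth(path: str | Path) -> dict:
    """Read a truth TSV back into ``{scaffold_lengths, truth_x, fusion, clusters}``."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "label": str})
    lengths = {
        r.scaffold: int(r.end)
        for r in df[df.record == "scaffold_length"].itertuples()
    }
    truth_x = set(df.loc[df.record == "x_scaffold", "scaffold"])
    fusion_rows = df[df.record == "fusion_segment"]
    fusion = (
        FusionMap(
            tuple(
                (r.scaffold, (int(r.start), int(r.end)), str(r.label))
                for r in fusion_rows.itertuples()
            )
        )
        if len(fusion_rows)
        else None
    )
    clusters = [
        (r.scaffold, int(r.start), int(r.end), str(r.label))
        for r in df[df.record == "tandem_cluster"].itertuples()
    ]
    return {
        "scaffold_lengths": lengths,
        "truth_x": truth_x,
        "fusion": fusion,
        "clusters": clusters,
    }
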