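"""One-command orchestration: simulate -> sexscan -> landscape -> paint.

A :class:`RunConfig` (YAML file plus flag overrides) drives the stages in
dependency order; every tabular output carries a ``#`` header with the
tool version, a config hash and the seed, and a run with identical
config and inputs is byte-identical. The end product is a per-scaffold
report joining sex call, landscape summaries and dominant reference
homology.
"""

from __future__ import annotations

import dataclasses
import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as kio
from . import landscape as ls
from . import sexscan as sx
from . import synteny_paint as sp
from . import synthetic_data as sd
from .windows import make_windows

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("karyoscope")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Configuration for a full run; defaults mirror the analysis defaults.

    Window sizes in bp; sexscan bands in log2 units; ``min_depth`` in raw
    mean-depth units; ``min_span_bp`` is the per-reference-chromosome
    span above which a scaffold's homology counts toward a fusion flag.
    """

    # inputs / outputs
    genome: str | None = None
    female: str | None = None
    male: str | None = None
    genes: str | None = None
    repeats: str | None = None
    orthologs: str | None = None
    out_dir: str = "karyoscope_out"
    # window sizes
    coverage_window: int = 100_000
    gc_window: int = 100_000
    gc_step: int = 1_000
    density_window: int = 100_000
    painting_window: int = 500_000
    # sexscan
    min_mapq: int = 0
    min_depth: float = 1.0
    x_band_low: float = 0.6
    x_band_high: float = 1.4
    autosome_band_low: float = -0.4
    autosome_band_high: float = 0.4
    min_unmasked_fraction: float = 0.5
    # clusters
    cluster_max_gap: int = 10_000
    cluster_min_size: int = 3
    # painting
    min_window_fraction: float = 0.5
    min_span_bp: int = 1_000_000
    # simulation
    simulate: bool = False
    depth_female: float = 20.0
    depth_male: float = 20.0
    read_length: int = 100
    ortholog_density: float = 80.0
    ortholog_dropout: float = 0.1
    seed: int = 0

    def digest(self) -> str:
        return kio.config_digest(dataclasses.asdict(self))

    def header_lines(self) -> list[str]:
        return [
            f"karyoscope v{__version__}",
            f"config={self.digest()}",
            f"seed={self.seed}",
        ]

    def check(self) -> None:
        problems = []
        for name in ("coverage_window", "gc_window", "gc_step", "density_window",
                     "painting_window"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.gc_step > self.gc_window:
            problems.append("gc_step must be <= gc_window")
        if not self.x_band_low < self.x_band_high:
            problems.append("x_band_low must be < x_band_high")
        if self.cluster_min_size < 2:
            problems.append("cluster_min_size must be >= 2")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides.

    Missing keys take their defaults; unknown keys and type mismatches
    are rejected, all violations reported at once, with a nearest-key
    suggestion for likely typos.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    problems = []
    clean: dict = {}
    for key, value in data.items():
        if key not in _FIELDS:
            hint = difflib.get_close_matches(key, _FIELDS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            problems.append(f"unknown key {key!r}{suffix}")
            continue
        ftype = _FIELDS[key].type
        try:
            clean[key] = _coerce(value, ftype, key)
        except (TypeError, ValueError) as exc:
            problems.append(str(exc))
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    config = RunConfig(**clean)
    config.check()
    return config


def _coerce(value, ftype: str, key: str):
    if value is None or "str" in ftype:
        return None if value is None else str(value)
    if ftype == "bool":
        if isinstance(value, bool):
            return value
        raise TypeError(f"{key} must be a boolean, got {value!r}")
    if ftype == "int":
        if isinstance(value, bool) or not isinstance(value, int):
            raise TypeError(f"{key} must be an integer, got {value!r}")
        return value
    if ftype == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeError(f"{key} must be a number, got {value!r}")
        return float(value)
    return value


# ---------------------------------------------------------------------------
# Stage plumbing

class _Stage:
    """Write stage outputs atomically: .partial during the stage, renamed on success."""

    def __init__(self, name: str, out_dir: Path, header: Sequence[str]):
        self.name = name
        self.out_dir = out_dir
        self.header = list(header)
        self._pending: list[tuple[Path, Path]] = []

    def write_tsv(self, frame: pd.DataFrame, filename: str) -> Path:
        final = self.out_dir / filename
        partial = final.with_suffix(final.suffix + ".partial")
        kio.write_tsv(frame, partial, header_lines=self.header)
        self._pending.append((partial, final))
        return final

    def write_bed(self, rows, filename: str) -> Path:
        final = self.out_dir / filename
        partial = final.with_suffix(final.suffix + ".partial")
        kio.write_bed3(rows, partial)
        self._pending.append((partial, final))
        return final

    def write_bedgraph(self, rows, filename: str) -> Path:
        final = self.out_dir / filename
        partial = final.with_suffix(final.suffix + ".partial")
        kio.write_bedgraph(rows, partial)
        self._pending.append((partial, final))
        return final

    def commit(self) -> None:
        for partial, final in self._pending:
            partial.replace(final)
        self._pending.clear()


def _require(config: RunConfig, fields: Sequence[str], stage: str) -> None:
    missing = [f for f in fields if getattr(config, f) is None]
    if missing:
        raise PipelineError(
            f"stage {stage}: missing required input field(s) {', '.join(missing)} "
            "(provide paths or use simulate)"
        )


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler) for h in log.handlers)
    if not log.handlers:
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
        log.addHandler(stream)
    if not have_file:
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
        log.addHandler(fh)


# ---------------------------------------------------------------------------
# The pipeline

def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the configured stages in dependency order.

    ``stages`` defaults to all of ``("simulate", "sexscan", "landscape",
    "paint")`` when simulation is requested, otherwise the three analysis
    stages reading the configured input paths. Returns a dict of
    in-memory results, including ``report`` (the per-scaffold summary
    DataFrame) when every analysis stage ran.
    """
    config.check()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    header = config.header_lines()

    analysis = ["sexscan", "landscape", "paint"]
    if stages is None:
        stages = (["simulate"] if config.simulate else []) + analysis
    results: dict = {"out_dir": out_dir}

    # ---- inputs ----------------------------------------------------------
    genome_seqs: dict[str, str] | None = None
    lengths: dict[str, int] | None = None
    reads_f = reads_m = None
    genes = repeats = None
    ortho_table: sp.OrthologTable | None = None

    if "simulate" in stages or config.simulate:
        log.info("stage simulate: generating toy genome (seed=%d)", config.seed)
        try:
            specs = sd.default_scaffold_specs()
            fusion = sd.default_fusion_map(specs)
            genome = sd.simulate_genome(specs, seed=config.seed)
            reads_f = sd.simulate_reads(
                genome, "female", config.depth_female, config.read_length,
                seed=config.seed + 1,
            )
            reads_m = sd.simulate_reads(
                genome, "male", config.depth_male, config.read_length,
                seed=config.seed + 2,
            )
            pairs = sd.simulate_orthologs(
                genome, fusion, n_per_mb=config.ortholog_density,
                dropout=config.ortholog_dropout, seed=config.seed + 3,
            )
            bundle = sd.write_fixture_bundle(
                genome, reads_f, reads_m, pairs, out_dir / "simulated", fusion
            )
        except Exception as exc:
            raise PipelineError(f"stage simulate: {exc}") from exc
        genome_seqs = genome.sequences
        lengths = genome.scaffold_lengths
        genes = genome.genes
        repeats = genome.repeats
        ortho_table = sp.OrthologTable.from_pairs(pairs)
        results.update(genome=genome, fixture_paths=bundle, truth_fusion=fusion)
    else:
        _require(config, ["genome"], "input")
        genome_seqs = kio.read_fasta(config.genome)
        lengths = {name: len(seq) for name, seq in genome_seqs.items()}

    # ---- sexscan ---------------------------------------------------------
    if "sexscan" in stages:
        stage = _Stage("sexscan", out_dir, header)
        log.info("stage sexscan: %d-bp windows", config.coverage_window)
        try:
            grid = make_windows(lengths, config.coverage_window)
            if reads_f is not None:
                cov_f = sx.coverage_from_placements(reads_f, grid)
                cov_m = sx.coverage_from_placements(reads_m, grid)
            else:
                _require(config, ["female", "male"], "sexscan")
                cov_f = sx.coverage_from_alignments(
                    config.female, grid, config.min_mapq, sample_label="female"
                )
                cov_m = sx.coverage_from_alignments(
                    config.male, grid, config.min_mapq, sample_label="male"
                )
            norm_f, norm_m = sx.normalize_pair(cov_f, cov_m)
            ratio = sx.ratio_track(norm_f, norm_m, min_depth=config.min_depth)
            calls = sx.call_scaffolds(
                ratio,
                x_band=(config.x_band_low, config.x_band_high),
                autosome_band=(config.autosome_band_low, config.autosome_band_high),
                min_unmasked_fraction=config.min_unmasked_fraction,
            )
            stage.write_tsv(sx.ratio_table(norm_f, norm_m, ratio), "sexscan_windows.tsv")
            stage.write_tsv(calls, "sex_calls.tsv")
            names = grid.window_scaffold_names()
            starts = grid.window_starts()
            ends = grid.window_ends()
            stage.write_bedgraph(
                (
                    (names[i], int(starts[i]), int(ends[i]), float(ratio.log2_ratio[i]))
                    for i in range(grid.n_windows)
                    if not ratio.masked[i]
                ),
                "log2_ratio.bedgraph",
            )
            stage.commit()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage sexscan: {exc}") from exc
        results.update(sex_calls=calls, ratio=ratio)

    # ---- landscape -------------------------------------------------------
    if "landscape" in stages:
        stage = _Stage("landscape", out_dir, header)
        log.info("stage landscape: GC %d/%d, density %d",
                 config.gc_window, config.gc_step, config.density_window)
        try:
            if genes is None:
                _require(config, ["genes", "repeats"], "landscape")
                genes = kio.read_gff3_genes(config.genes)
                repeats = kio.read_bed3(config.repeats)
            gc_frames = []
            for name, seq in genome_seqs.items():
                track = ls.gc_sliding(seq, config.gc_window, config.gc_step)
                frame = track.to_frame()
                frame["scaffold"] = name
                gc_frames.append(frame)
            gc_all = pd.concat(gc_frames, ignore_index=True)
            grid = make_windows(lengths, config.density_window)
            gene_density = ls.feature_density(genes, grid, feature_kind="gene")
            repeat_density = ls.feature_density(repeats, grid, feature_kind="repeat")
            stats = ls.assembly_stats(genome_seqs)
            families = sorted({g[5] for g in genes} - {"."})
            clusters = []
            for fam in families:
                fam_genes = [(g[0], g[1], g[2], g[4]) for g in genes if g[5] == fam]
                cs = ls.find_clusters(
                    fam_genes, config.cluster_max_gap, config.cluster_min_size
                )
                clusters.extend(cs.clusters)
            stage.write_tsv(gc_all, "gc_track.tsv")
            stage.write_tsv(gene_density.to_frame(), "gene_density.tsv")
            stage.write_tsv(repeat_density.to_frame(), "repeat_density.tsv")
            stage.write_tsv(
                pd.DataFrame([dataclasses.asdict(stats)]), "assembly_stats.tsv"
            )
            stage.write_bed(
                [(c.scaffold, c.start, c.end, ",".join(c.members)) for c in clusters],
                "gene_clusters.bed",
            )
            stage.commit()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage landscape: {exc}") from exc
        results.update(
            gene_density=gene_density, repeat_density=repeat_density,
            assembly_stats=stats, clusters=clusters, gc=gc_all,
        )

    # ---- paint -----------------------------------------------------------
    if "paint" in stages:
        stage = _Stage("paint", out_dir, header)
        log.info("stage paint: %d-bp windows", config.painting_window)
        try:
            if ortho_table is None:
                _require(config, ["orthologs"], "paint")
                ortho_table = sp.load_orthologs(config.orthologs, lengths)
            grid = make_windows(lengths, config.painting_window)
            matrix = sp.paint(ortho_table, grid)
            homology = sp.summarize_homology(
                matrix, config.min_span_bp, config.min_window_fraction
            )
            stage.write_tsv(matrix.to_frame(), "painting.tsv")
            stage.write_tsv(homology, "homology.tsv")
            stage.commit()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage paint: {exc}") from exc
        results.update(painting=matrix, homology=homology)

    # ---- combined report -------------------------------------------------
    if all(s in stages for s in analysis):
        stage = _Stage("report", out_dir, header)
        try:
            report = _scaffold_report(
                lengths, genome_seqs, results["sex_calls"],
                results["gene_density"], results["repeat_density"],
                results["homology"],
            )
            stage.write_tsv(report, "scaffold_report.tsv")
            stage.commit()
        except Exception as exc:
            raise PipelineError(f"stage report: {exc}") from exc
        results["report"] = report
        log.info("run complete: %d scaffolds reported", len(report))
    return results


def _scaffold_report(
    lengths: Mapping[str, int],
    sequences: Mapping[str, str],
    calls: pd.DataFrame,
    gene_density: ls.DensityTrack,
    repeat_density: ls.DensityTrack,
    homology: pd.DataFrame,
) -> pd.DataFrame:
    """Join the stage outputs into one row per scaffold, without recomputation."""
    rows = []
    calls_ix = calls.set_index("scaffold")
    hom_ix = homology.set_index("scaffold")
    for name in lengths:
        sl = gene_density.grid.scaffold_slice(name)
        gc_count, valid = ls._gc_of(sequences[name])
        rows.append(
            {
                "scaffold": name,
                "length": lengths[name],
                "sex_call": calls_ix.loc[name, "call"],
                "median_log2_fm": calls_ix.loc[name, "median_log2_ratio"],
                "gene_count": int(gene_density.counts[sl].sum()),
                "repeat_count": int(repeat_density.counts[sl].sum()),
                "mean_gc": gc_count / valid if valid else np.nan,
                "dominant_ref": hom_ix.loc[name, "dominant_ref"],
                "fusion_flag": bool(hom_ix.loc[name, "fusion_flag"]),
            }
        )
    return pd.DataFrame(rows)
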