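"""End-to-end orchestration: simulate -> normalize -> subtract -> detect ->
select -> classify -> scan -> CTCF -> conservation -> expression -> report.

Every run is driven by a single :class:`RunConfig` (loadable from YAML) and
one root seed; all randomness flows from per-stage streams derived from it,
so a repeated run writes byte-identical outputs. The summary report mirrors
the count/percentage tables of the analysis: peaks per fraction, the
G1/G2/GIS partition, motif-presence fractions, CTCF sets l/k/n with motif
percentages, conservation bins, and DEG group sizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import io as gio
from .coverage import normalize_coverage, subtract_control
from .expression import (
    assign_regions,
    bin_deg_by_binding,
    bin_deg_by_conservation,
    build_neighborhoods,
    call_deg,
)
from .motif import matrix_from_iupac, motif_presence
from .peaks import detect_enriched_regions, intensity_cutoff, select_peaks
from .regions import (
    classify_gli,
    conservation_bins,
    ctcf_colocalize,
    filter_mouse_intensity,
    overlaps_any,
)
from .simulate import StudyConfig, simulate_study


def percentage(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("percentage undefined for non-positive denominator")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _safe_percentage(numerator: int, denominator: int) -> float | None:
    return percentage(numerator, denominator) if denominator > 0 else None


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Distances and bandwidth are in bp; match thresholds are matrix-similarity
    scores in [0, 1] compared strictly; fc_threshold is a linear fold change;
    gli3_cutoff is an intensity score.
    """

    seed: int = 0
    distance: int = 250
    bandwidth: int = 250
    min_width: int = 50
    background: float | str = "auto"
    flank: int = 250
    gli_consensus: str = "GACCACCCA"
    ctcf_consensus: str = "CCMMYYCHHGGTGG"
    gli_threshold: float = 0.95
    ctcf_threshold: float = 0.65
    fc_threshold: float = 1.5
    alpha: float = 0.05
    gli3_cutoff: float = 3.0
    neighbors_per_side: int = 1
    simulate: StudyConfig | None = field(default_factory=StudyConfig)
    inputs: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.distance < 0 or self.flank < 0:
            raise ValueError("distances must be non-negative")
        if self.bandwidth <= 0 or self.min_width <= 0:
            raise ValueError("bandwidth and min_width must be positive")
        for name in ("gli_threshold", "ctcf_threshold"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.neighbors_per_side < 1:
            raise ValueError("neighbors_per_side must be >= 1")
        if self.background != "auto":
            self.background = float(self.background)
        if self.simulate is None and self.inputs is None:
            raise ValueError("either a simulate block or input paths are required")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", "default")
        if sim == "default":
            simulate = StudyConfig()
        elif sim is None:
            simulate = None
        elif isinstance(sim, StudyConfig):
            simulate = sim
        else:
            simulate = StudyConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulate=simulate, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


@dataclass
class PipelineInputs:
    genome_sequence: dict[str, str]
    g1_track: Any
    g2_track: Any
    control_track: Any
    conserved: list
    ctcf: list
    mouse_g1: list
    mouse_g3: list
    genes: list
    expression: pd.DataFrame


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_simulated_inputs(config: RunConfig, outdir: Path) -> dict[str, Any]:
    study = simulate_study(config.simulate, seed=config.seed)
    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    gio.write_fasta(study.genome.sequence, inputs_dir / "genome.fa")
    gio.write_bedgraph(study.g1_track, inputs_dir / "gli1.bedgraph")
    gio.write_bedgraph(study.g2_track, inputs_dir / "gli2.bedgraph")
    gio.write_bedgraph(study.control_track, inputs_dir / "igg.bedgraph")
    gio.write_bed(study.truth.conserved_elements, inputs_dir / "conserved.bed")
    gio.write_bed(study.truth.ctcf_regions, inputs_dir / "ctcf.bed")
    gio.write_bed(study.truth.mouse_regions["mG1"], inputs_dir / "mouse_gli1.bed")
    gio.write_bed(study.truth.mouse_regions["mG3"], inputs_dir / "mouse_gli3.bed")
    gio.write_genes(study.genes, inputs_dir / "genes.tsv")
    gio.write_table(study.expression, inputs_dir / "expression.tsv")
    (inputs_dir / "truth.json").write_text(study.truth.to_json())
    return {
        "genome_fasta": str(inputs_dir / "genome.fa"),
        "g1_bedgraph": str(inputs_dir / "gli1.bedgraph"),
        "g2_bedgraph": str(inputs_dir / "gli2.bedgraph"),
        "control_bedgraph": str(inputs_dir / "igg.bedgraph"),
        "g1_library_size": study.g1_track.library_size,
        "g2_library_size": study.g2_track.library_size,
        "control_library_size": study.control_track.library_size,
        "conserved_bed": str(inputs_dir / "conserved.bed"),
        "ctcf_bed": str(inputs_dir / "ctcf.bed"),
        "mouse_g1_bed": str(inputs_dir / "mouse_gli1.bed"),
        "mouse_g3_bed": str(inputs_dir / "mouse_gli3.bed"),
        "genes_tsv": str(inputs_dir / "genes.tsv"),
        "expression_tsv": str(inputs_dir / "expression.tsv"),
    }


def load_inputs(paths: Mapping[str, Any]) -> PipelineInputs:
    sequence = gio.read_fasta(paths["genome_fasta"])
    lengths = {c: len(s) for c, s in sequence.items()}
    return PipelineInputs(
        genome_sequence=sequence,
        g1_track=gio.read_bedgraph(paths["g1_bedgraph"], lengths, int(paths["g1_library_size"])),
        g2_track=gio.read_bedgraph(paths["g2_bedgraph"], lengths, int(paths["g2_library_size"])),
        control_track=gio.read_bedgraph(
            paths["control_bedgraph"], lengths, int(paths["control_library_size"])
        ),
        conserved=gio.read_bed(paths["conserved_bed"]),
        ctcf=gio.read_bed(paths["ctcf_bed"]),
        mouse_g1=gio.read_bed(paths["mouse_g1_bed"]),
        mouse_g3=gio.read_bed(paths["mouse_g3_bed"]),
        genes=gio.read_genes(paths["genes_tsv"]),
        expression=gio.read_table(paths["expression_tsv"]),
    )


def _class_presence(regions, genome, matrix, flank, threshold):
    if not regions:
        return None, 0
    fraction, flags = motif_presence(regions, genome, matrix, flank, threshold)
    return fraction, sum(flags)


def run_pipeline(config: RunConfig, outdir) -> dict[str, Any]:
    """Execute all stages and return the summary report (also written to
    ``outdir`` as report.json and report.tsv alongside intermediate files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            paths = _write_simulated_inputs(config, outdir)
        else:
            paths = dict(config.inputs)

        stage = "load"
        data = load_inputs(paths)
        genome = data.genome_sequence

        stage = "normalize"
        g1 = normalize_coverage(data.g1_track)
        g2 = normalize_coverage(data.g2_track)
        control = normalize_coverage(data.control_track)

        stage = "subtract"
        g1 = subtract_control(g1, control)
        g2 = subtract_control(g2, control)

        stage = "detect"
        detected = {
            "GLI1": detect_enriched_regions(
                g1, config.bandwidth, config.background, config.min_width, fraction="GLI1"
            ),
            "GLI2": detect_enriched_regions(
                g2, config.bandwidth, config.background, config.min_width, fraction="GLI2"
            ),
        }
        for label, peaks in detected.items():
            gio.write_peaks_bed(peaks, outdir / f"peaks_{label.lower()}_detected.bed")

        stage = "select"
        selected = {
            "GLI1": select_peaks(
                detected["GLI1"], data.conserved, detected["GLI2"], config.distance
            ),
            "GLI2": select_peaks(
                detected["GLI2"], data.conserved, detected["GLI1"], config.distance
            ),
        }
        intensity_stats = {}
        for label, peaks in detected.items():
            if len(peaks) >= 2:
                mean, sd, cutoff = intensity_cutoff([p.intensity for p in peaks])
                intensity_stats[label] = {"mean": mean, "sd": sd, "cutoff": cutoff}
            gio.write_peaks_bed(selected[label], outdir / f"peaks_{label.lower()}_selected.bed")

        stage = "classify"
        partition = classify_gli(selected["GLI1"], selected["GLI2"], config.distance)
        gio.write_bed(partition.gis, outdir / "gis.bed")

        stage = "scan"
        gli_matrix = matrix_from_iupac(config.gli_consensus, name="GLI")
        presence: dict[str, Any] = {}
        for label, regions in partition.class_regions().items():
            fraction, n_hits = _class_presence(
                regions, genome, gli_matrix, config.flank, config.gli_threshold
            )
            presence[label] = {
                "total": len(regions),
                "with_motif": n_hits,
                "percent": _safe_percentage(n_hits, len(regions)),
            }

        stage = "ctcf"
        coloc = ctcf_colocalize(partition, data.ctcf, config.distance)
        ctcf_matrix = matrix_from_iupac(config.ctcf_consensus, name="CTCF")
        ctcf_report: dict[str, Any] = {}
        for key, regions in (("l", coloc.l), ("k", coloc.k), ("n", coloc.n)):
            _, n_hits = _class_presence(
                regions, genome, ctcf_matrix, config.flank, config.ctcf_threshold
            )
            ctcf_report[key] = {
                "count": coloc.counts[key],
                "total": coloc.totals[key],
                "percent_of_class": _safe_percentage(coloc.counts[key], coloc.totals[key]),
                "with_ctcf_motif": n_hits,
                "motif_percent": _safe_percentage(n_hits, coloc.counts[key]),
            }

        stage = "conserve"
        mg3_kept = filter_mouse_intensity(data.mouse_g3, config.gli3_cutoff)
        bins = conservation_bins(
            selected["GLI1"], selected["GLI2"], data.mouse_g1, mg3_kept, config.distance
        )
        for letter, regions in sorted(bins.bins.items()):
            gio.write_bed(regions, outdir / f"conservation_bin_{letter}.bed")

        stage = "integrate"
        lengths = {c: len(s) for c, s in genome.items()}
        deg = call_deg(data.expression, config.fc_threshold, config.alpha)
        neighborhoods = build_neighborhoods(data.genes, lengths, config.neighbors_per_side)
        labels = assign_regions(partition.class_regions(), neighborhoods)
        groups = bin_deg_by_binding(deg, labels)
        conserved_g1 = [
            p for p, f in zip(selected["GLI1"], overlaps_any(selected["GLI1"], data.conserved)) if f
        ] if selected["GLI1"] else []
        conserved_g2 = [
            p for p, f in zip(selected["GLI2"], overlaps_any(selected["GLI2"], data.conserved)) if f
        ] if selected["GLI2"] else []
        cons_labels = assign_regions(
            {"hG1": conserved_g1, "hG2": conserved_g2, "mG1": data.mouse_g1, "mG3": mg3_kept},
            neighborhoods,
        )
        flags = {
            gene: {k: k in lbls for k in ("hG1", "hG2", "mG1", "mG3")}
            for gene, lbls in cons_labels.items()
        }
        conserved_sets = bin_deg_by_conservation(deg, flags)

        stage = "report"
        gene_rows = []
        group_of = {r.gene_id: g for g, recs in groups.items() for r in recs}
        conset_of = {r.gene_id: s for s, recs in conserved_sets.items() for r in recs}
        for record in deg:
            gene_rows.append(
                {
                    "gene_id": record.gene_id,
                    "deg_status": record.deg_status,
                    "log2fc": round(record.log2fc, 6),
                    "p_value": round(record.p_value, 8),
                    "binding_labels": ",".join(sorted(labels.get(record.gene_id, ()))) or ".",
                    "group": group_of.get(record.gene_id, "."),
                    "conserved_set": conset_of.get(record.gene_id, "."),
                }
            )
        gio.write_table(pd.DataFrame(gene_rows), outdir / "genes_classified.tsv")

        n_up = sum(1 for r in deg if r.deg_status == "up")
        n_down = sum(1 for r in deg if r.deg_status == "down")
        report: dict[str, Any] = {
            "parameters": {
                "seed": config.seed,
                "distance": config.distance,
                "bandwidth": config.bandwidth,
                "min_width": config.min_width,
                "flank": config.flank,
                "gli_threshold": config.gli_threshold,
                "ctcf_threshold": config.ctcf_threshold,
                "fc_threshold": config.fc_threshold,
                "alpha": config.alpha,
                "gli3_cutoff": config.gli3_cutoff,
            },
            "peaks": {
                label: {
                    "detected": len(detected[label]),
                    "selected": len(selected[label]),
                    "intensity_mean": round(intensity_stats[label]["mean"], 4)
                    if label in intensity_stats
                    else None,
                    "intensity_sd": round(intensity_stats[label]["sd"], 4)
                    if label in intensity_stats
                    else None,
                }
                for label in ("GLI1", "GLI2")
            },
            "partition": {
                "G1_only": partition.counts["G1"],
                "G2_only": partition.counts["G2"],
                "GIS": partition.counts["GIS"],
                "GIS_member_peaks": len(partition.gis_members),
                "selected_total": len(selected["GLI1"]) + len(selected["GLI2"]),
            },
            "gli_motif_presence": presence,
            "ctcf": ctcf_report,
            "conservation": {
                "mouse_g3_total": len(data.mouse_g3),
                "mouse_g3_kept": len(mg3_kept),
                "mouse_g3_kept_percent": _safe_percentage(len(mg3_kept), len(data.mouse_g3)),
                "bin_counts": dict(sorted(bins.counts.items())),
            },
            "expression": {
                "n_genes": len(deg),
                "upregulated": n_up,
                "downregulated": n_down,
                "deg_with_binding": sum(len(v) for v in groups.values()),
                "deg_groups": {k: len(v) for k, v in sorted(groups.items())},
                "conserved_sets": {k: len(v) for k, v in sorted(conserved_sets.items())},
            },
        }
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    flat = _flatten(report)
    with open(outdir / "report.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in flat:
            fh.write(f"{key}\t{value}\n")
    return report


def _flatten(obj: Any, prefix: str = "") -> list[tuple[str, Any]]:
    rows: list[tuple[str, Any]] = []
    if isinstance(obj, Mapping):
        for key in sorted(obj):
            rows.extend(_flatten(obj[key], f"{prefix}{key}." if prefix or True else key))
    else:
        rows.append((prefix.rstrip("."), obj))
    return rows
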