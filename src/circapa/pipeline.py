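"""End-to-end orchestration: simulate -> psi -> filter -> rhythm ->
characterize, with a manifest and (on synthetic data) a truth-vs-detected
evaluation.

A run is fully determined by its :class:`RunConfig` (including the
seed): two runs with identical configs produce byte-identical manifests
and reports.  Stage survivor counts are reconciled in the manifest so
that counts-in equal counts-out plus removals at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import CountsTable, compute_tpm, read_counts, read_three_prime_annotation
from .characterize import characterization_report
from .filtering import FilterReport, compute_apa_index, filter_isoforms, filter_low_coverage, top_two_from_psi_matrix
from .psi import estimate_psi_series
from .rhythm import DEFAULT_PERIOD_STEP, DEFAULT_PERIOD_WINDOW, detect_rhythms
from .simulate import SimConfig, TruthRecord, read_truth, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Either ``sim`` (synthetic mode, with ground truth) or the three
    explicit input paths (real-counts mode, no truth) must be set.
    """

    sim: SimConfig | None = None
    annotation_path: str | None = None
    fasta_path: str | None = None
    counts_path: str | None = None
    out_dir: str = "circapa_run"
    min_reads: int = 20
    coverage_mode: str = "per_timepoint"
    min_mean_psi: float = 0.1
    min_mean_tpm: float = 1.0
    n_perm: int = 999
    period_window: tuple[float, float] = DEFAULT_PERIOD_WINDOW
    period_step: float = DEFAULT_PERIOD_STEP
    threshold_preset: str = "default"
    series_kind: str = "apa_index"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        config = cls(**{k: v for k, v in raw.items() if k != "period_window"})
        if "period_window" in raw:
            config.period_window = tuple(raw["period_window"])
        if sim_raw is not None:
            if "amplitude_range" in sim_raw:
                sim_raw["amplitude_range"] = tuple(sim_raw["amplitude_range"])
            config.sim = SimConfig(**sim_raw)
        return config

    def validate(self) -> None:
        if self.sim is None and not (self.annotation_path and self.fasta_path and self.counts_path):
            raise ValueError("either a SimConfig or annotation/fasta/counts paths are required")


@dataclass(frozen=True)
class EvaluationResult:
    """Truth-vs-detected confusion summary for rhythmic-gene detection.

    Restricted metrics only count genes that survived every filter (a
    rhythmic gene killed by a coverage or expression filter is not a
    detector miss); unrestricted sensitivity divides by all planted
    rhythmic genes.  Phase errors are circular distances in hours.
    """

    sensitivity: float
    specificity: float
    fdr: float
    unrestricted_sensitivity: float
    n_analyzed: int
    n_true_rhythmic_analyzed: int
    n_detected: int
    phase_error_hours_median: float | None
    phase_error_hours_q90: float | None
    period_error_hours_median: float | None
    amplitude_error_median: float | None


def circular_error(a: float, b: float, period: float = 24.0) -> float:
    """Minimal circular distance between two phases, in hours."""
    d = abs(a - b) % period
    return min(d, period - d)


def evaluate_against_truth(
    rhythm: pd.DataFrame,
    truth: Sequence[TruthRecord],
    analyzed_genes: Sequence[str] | None = None,
    period: float = 24.0,
) -> EvaluationResult:
    """Compare detector output against the generator's truth table.

    ``rhythm`` must carry ``gene_id, rhythmic`` and, for detections,
    ``phase_ct, best_period, amplitude``.  The detected APA-index
    amplitude is compared against twice the planted psi amplitude
    (APA index = 2*psi_prox - 1).
    """
    truth_by_id = {r.gene_id: r for r in truth}
    rhythm_genes = set(rhythm["gene_id"])
    if not rhythm_genes & set(truth_by_id):
        raise ValueError("truth table and rhythm results share no genes")
    missing = sorted(rhythm_genes - set(truth_by_id))
    if missing:
        raise ValueError(f"truth table does not cover genes {missing}")

    if analyzed_genes is None:
        analyzed = sorted(rhythm_genes)
    else:
        analyzed = sorted(set(analyzed_genes))
    detected = rhythm[rhythm["rhythmic"]].drop_duplicates(subset=["gene_id"])
    detected_ids = set(detected["gene_id"])

    true_pos_ids = {g for g in analyzed if truth_by_id[g].is_rhythmic}
    true_neg_ids = set(analyzed) - true_pos_ids
    tp = len(true_pos_ids & detected_ids)
    fn = len(true_pos_ids - detected_ids)
    fp = len(true_neg_ids & detected_ids)
    tn = len(true_neg_ids - detected_ids)

    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    all_true = [r.gene_id for r in truth if r.is_rhythmic]
    unrestricted = len(set(all_true) & detected_ids) / len(all_true) if all_true else float("nan")

    phase_err, period_err, amp_err = [], [], []
    for row in detected.itertuples(index=False):
        rec = truth_by_id[row.gene_id]
        if not rec.is_rhythmic:
            continue
        phase_err.append(circular_error(row.phase_ct, rec.phase_true, period))
        period_err.append(abs(row.best_period - period))
        amp_err.append(abs(row.amplitude - 2.0 * rec.amplitude))

    def q(vals, p):
        return float(np.quantile(vals, p)) if vals else None

    return EvaluationResult(
        sensitivity=sensitivity,
        specificity=specificity,
        fdr=fdr,
        unrestricted_sensitivity=unrestricted,
        n_analyzed=len(analyzed),
        n_true_rhythmic_analyzed=len(true_pos_ids),
        n_detected=len(detected_ids),
        phase_error_hours_median=q(phase_err, 0.5),
        phase_error_hours_q90=q(phase_err, 0.9),
        period_error_hours_median=q(period_err, 0.5),
        amplitude_error_median=q(amp_err, 0.5),
    )


@dataclass
class RunResult:
    manifest: dict
    report: dict
    evaluation: EvaluationResult | None
    rhythm: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_end_to_end(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the report bundle.

    Output files: psi.tsv, pairs.tsv, apa_index.tsv, rhythm.tsv,
    filter_report.json, report.json, manifest.json (plus, in synthetic
    mode, the generated dataset under ``data/``).  Any stage error
    propagates with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.sim is not None:
            stage = "simulate"
            annotation, truth, counts = simulate_dataset(config.sim)
            data_paths = write_dataset(annotation, truth, counts, out / "data")
            # read back through the I/O layer so the run exercises it
            stage = "read"
            tandem, single = read_three_prime_annotation(data_paths["gff3"], data_paths["fasta"])
            counts = read_counts(data_paths["counts"])
            truth = read_truth(data_paths["truth"])
        else:
            stage = "read"
            tandem, single = read_three_prime_annotation(config.annotation_path, config.fasta_path)
            counts = read_counts(config.counts_path)
            truth = None

        stage = "tpm"
        tpm = compute_tpm(counts, list(tandem) + list(single))

        stage = "psi"
        tandem_ids = {g.gene_id for g in tandem}
        tandem_counts = CountsTable(counts.frame[counts.frame["gene_id"].isin(tandem_ids)])
        psi = estimate_psi_series(tandem_counts, tandem)

        stage = "filter"
        report_obj = FilterReport()
        survivors, _ = filter_low_coverage(
            tandem_counts, config.min_reads, config.coverage_mode, report_obj
        )
        survivors, _ = filter_isoforms(
            psi,
            tpm,
            counts.n_cycles,
            config.min_mean_psi,
            config.min_mean_tpm,
            genes=survivors,
            report=report_obj,
        )
        pairs, dropped = top_two_from_psi_matrix(psi, survivors)
        report_obj.add_stage("top_two_pairs", survivors, pairs["pair_id"].tolist(), dropped)

        stage = "apa_index"
        apa = compute_apa_index(psi, pairs)

        stage = "rhythm"
        rhythm = detect_rhythms(
            apa,
            value_col="apa_index",
            id_col="pair_id",
            n_perm=config.n_perm,
            seed=config.seed,
            window=config.period_window,
            step=config.period_step,
            series_kind=config.series_kind,
            preset=config.threshold_preset,
        )
        rhythm = rhythm.merge(pairs[["pair_id", "gene_id"]], on="pair_id")

        stage = "characterize"
        report = characterization_report(tandem, single, pairs, psi.mean_psi(), apa, rhythm)

        stage = "evaluate"
        evaluation = None
        if truth is not None:
            evaluation = evaluate_against_truth(rhythm, truth, analyzed_genes=survivors)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage_counts = report_obj.survivors_per_stage()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_cycles": counts.n_cycles,
        "time_grid": counts.time_grid.tolist(),
        "stages": report_obj.to_dict(),
        "stage_survivors": stage_counts,
        "n_genes_input": len(tandem) + len(single),
        "n_tandem_genes": len(tandem),
        "n_pairs_tested": int(len(pairs)),
        "n_rhythmic_pairs": int(rhythm["rhythmic"].sum()),
    }
    if evaluation is not None:
        manifest["evaluation"] = asdict(evaluation)

    paths = {
        "psi": out / "psi.tsv",
        "pairs": out / "pairs.tsv",
        "apa_index": out / "apa_index.tsv",
        "rhythm": out / "rhythm.tsv",
        "filter_report": out / "filter_report.json",
        "report": out / "report.json",
        "manifest": out / "manifest.json",
    }
    psi.to_tsv(paths["psi"])
    pairs.to_csv(paths["pairs"], sep="\t", index=False)
    apa.to_csv(paths["apa_index"], sep="\t", index=False)
    rhythm.to_csv(paths["rhythm"], sep="\t", index=False)
    _dump_json(report_obj.to_dict(), paths["filter_report"])
    _dump_json(report, paths["report"])
    _dump_json(manifest, paths["manifest"])
    logger.info(
        "run complete: %d tandem genes, %d pairs tested, %d rhythmic",
        len(tandem), len(pairs), int(rhythm["rhythmic"].sum()),
    )
    return RunResult(manifest, report, evaluation, rhythm, paths)
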