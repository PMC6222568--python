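"""Synthetic tandem-UTR datasets with known ground truth.

The generator emulates the statistical structure of circadian liver
RNA-seq time courses at the level of 3'UTR segment counts: a configurable
fraction of genes carries two tandem poly(A) sites, a minority of those
oscillates its proximal/distal usage with a ~24 h period, segment read
counts follow a Poisson-total / binomial-split noise model, and poly(A)
signal hexamers (AATAAA / ATTAAA in DNA alphabet) are planted within
40 nt upstream of cleavage sites on an otherwise motif-free background.

The noise model is the minimal one consistent with uniform read sampling
over isoforms: with long-isoform fraction theta = 1 - psi_prox, common
length L_c and extension length L_e, a read falls in the extension with
probability ``p_ext = theta * L_e / (L_c + theta * L_e)``.  The
closed-form psi estimator in :mod:`circapa.psi` is the exact maximum
likelihood inverse of this model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    CountsTable,
    SingleSiteGene,
    TandemUTRGene,
    reverse_complement,
    write_fasta,
    write_gff3,
)

logger = logging.getLogger(__name__)

CANONICAL_PAS = "AATAAA"
VARIANT_PAS = "ATTAAA"

#: study designs: name -> (number of circadian cycles, sampling interval in h)
DESIGNS = {
    "1-cycle/3h": (1, 3.0),
    "2-cycle/4h": (2, 4.0),
    "2-cycle/6h": (2, 6.0),
}

# minimum segment length: a full 40-nt PAS scan window plus the hexamer
_MIN_SEG_LEN = 46
# planted hexamers end 10-30 nt upstream of the cleavage site
_PLANT_OFFSET_RANGE = (10, 30)
_CONTIG_PAD = 25


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic circadian APA dataset.

    Defaults mirror the liver datasets the generator emulates: 57.4% of
    genes multi-PAS, a short-isoform 3'UTR median of 768 nt and a
    long-isoform median of 1800 nt, 24 h true period, and a rhythmic
    minority of 5% of multi-PAS genes (~2.9% of all genes).
    """

    n_genes: int = 2000
    frac_multi_pas: float = 0.574
    frac_rhythmic: float = 0.05
    design: str = "2-cycle/4h"
    sampling_start_ct: float = 0.0
    reads_per_gene_mean: float = 200.0
    library_size: int = 1_000_000
    common_len_median: float = 768.0
    total_long_len_median: float = 1800.0
    len_sigma: float = 0.45
    expr_sigma: float = 2.0
    pas_canonical_prob_proximal: float = 0.35
    pas_variant_prob_proximal: float = 0.25
    pas_canonical_prob_distal: float = 0.55
    pas_variant_prob_distal: float = 0.18
    pas_canonical_prob_single: float = 0.64
    pas_variant_prob_single: float = 0.18
    amplitude_range: tuple[float, float] = (0.1, 0.3)
    period_true: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        for name in (
            "frac_multi_pas",
            "frac_rhythmic",
            "pas_canonical_prob_proximal",
            "pas_variant_prob_proximal",
            "pas_canonical_prob_distal",
            "pas_variant_prob_distal",
            "pas_canonical_prob_single",
            "pas_variant_prob_single",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        for site in ("proximal", "distal", "single"):
            tot = getattr(self, f"pas_canonical_prob_{site}") + getattr(self, f"pas_variant_prob_{site}")
            if tot > 1.0 + 1e-12:
                raise InvalidConfigError(f"PAS class probabilities for {site} site sum to {tot} > 1")
        if self.design not in DESIGNS:
            raise InvalidConfigError(f"unknown design {self.design!r}; choose from {sorted(DESIGNS)}")
        lo, hi = self.amplitude_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("amplitude_range must lie within (0, 0.5]")
        if self.period_true <= 0:
            raise InvalidConfigError("period_true must be positive")
        if len(self.time_grid()) < 4:
            raise InvalidConfigError("design must yield at least 4 time points")

    def time_grid(self) -> np.ndarray:
        n_cycles, interval = DESIGNS[self.design]
        n_points = int(round(n_cycles * 24.0 / interval))
        return self.sampling_start_ct + interval * np.arange(n_points)


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth psi trajectory for one simulated gene."""

    gene_id: str
    is_multi_pas: bool
    is_rhythmic: bool
    baseline_psi_prox: float
    amplitude: float
    phase_true: float
    psi_prox_by_time: tuple[float, ...]


@dataclass(frozen=True)
class PlantedPAS:
    """Ground truth for one planted (or absent) poly(A) signal hexamer.

    ``offset`` is the number of nucleotides between the hexamer's last
    base and the cleavage site (None when no hexamer was planted).
    """

    gene_id: str
    site: str
    hexamer: str | None
    offset: int | None


@dataclass(frozen=True)
class SimulatedAnnotation:
    """Annotation bundle produced by :func:`generate_annotation`."""

    tandem_genes: tuple[TandemUTRGene, ...]
    single_genes: tuple[SingleSiteGene, ...]
    contigs: dict[str, str] = field(compare=False)
    pas_truth: tuple[PlantedPAS, ...] = ()

    @property
    def all_gene_ids(self) -> list[str]:
        return sorted([g.gene_id for g in self.tandem_genes] + [g.gene_id for g in self.single_genes])


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([stream, config.seed])


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _find_motifs(seq: str) -> list[int]:
    hits = []
    for motif in (CANONICAL_PAS, VARIANT_PAS):
        start = seq.find(motif)
        while start != -1:
            hits.append(start)
            start = seq.find(motif, start + 1)
    return sorted(set(hits))


def _scrub_motifs(seq: str, rng: np.random.Generator, protected: Sequence[tuple[int, int]] = ()) -> str:
    """Re-randomize bases until the sequence carries no PAS hexamer outside
    the protected spans.  Bases inside protected spans are never touched."""
    prot = sorted(protected)

    def shielded(pos: int) -> bool:
        return any(s <= pos < e for s, e in prot)

    chars = list(seq)
    while True:
        hits = [h for h in _find_motifs("".join(chars)) if (h, h + 6) not in prot]
        hits = [h for h in hits if not all(shielded(p) for p in range(h, h + 6))]
        if not hits:
            return "".join(chars)
        for h in hits:
            for p in range(h, h + 6):
                if not shielded(p):
                    chars[p] = "ACGT"[rng.integers(0, 4)]


def _draw_pas_class(rng: np.random.Generator, p_canonical: float, p_variant: float) -> str | None:
    u = rng.random()
    if u < p_canonical:
        return CANONICAL_PAS
    if u < p_canonical + p_variant:
        return VARIANT_PAS
    return None


def _plant_site(
    chars: list[str],
    cleavage_offset: int,
    hexamer: str | None,
    rng: np.random.Generator,
) -> tuple[tuple[int, int] | None, int | None]:
    """Plant ``hexamer`` so that its last base lies ``off`` nt upstream of
    the cleavage position; return (protected span, offset)."""
    if hexamer is None:
        return None, None
    off = int(rng.integers(_PLANT_OFFSET_RANGE[0], _PLANT_OFFSET_RANGE[1] + 1))
    end = cleavage_offset - off
    start = end - 6
    chars[start:end] = list(hexamer)
    return (start, end), off


def _draw_length(rng: np.random.Generator, median: float, sigma: float, minimum: int) -> int:
    while True:
        val = int(round(math.exp(rng.normal(math.log(median), sigma))))
        if val >= minimum:
            return val


def generate_annotation(config: SimConfig) -> SimulatedAnnotation:
    """Generate tandem-UTR genes, single-site genes and their contigs.

    Exactly ``round(n_genes * frac_multi_pas)`` genes receive a tandem
    proximal/distal site pair (deterministic rounding, so fixture counts
    are exact).  Common and extension lengths are log-normal around the
    configured medians; every 40-nt scan window upstream of a cleavage
    site carries at most the single planted hexamer, and the remaining
    UTR background is rejection-sampled to be free of AATAAA/ATTAAA.
    """
    config.validate()
    rng = _rng(config, 0)
    n_multi = int(round(config.n_genes * config.frac_multi_pas))
    multi_idx = set(rng.choice(config.n_genes, size=n_multi, replace=False).tolist())

    tandem: list[TandemUTRGene] = []
    single: list[SingleSiteGene] = []
    contigs: dict[str, str] = {}
    pas_truth: list[PlantedPAS] = []
    for i in range(config.n_genes):
        gene_id = f"g{i:05d}"
        contig = f"ctg_{gene_id}"
        strand = "+" if rng.random() < 0.5 else "-"
        is_multi = i in multi_idx
        if is_multi:
            l_c = _draw_length(rng, config.common_len_median, config.len_sigma, _MIN_SEG_LEN)
            while True:
                total = _draw_length(rng, config.total_long_len_median, config.len_sigma, 1)
                l_e = total - l_c
                if l_e >= _MIN_SEG_LEN:
                    break
            utr_len = l_c + l_e
        else:
            l_c = _draw_length(rng, config.common_len_median, config.len_sigma, _MIN_SEG_LEN)
            l_e = 0
            utr_len = l_c

        utr = _scrub_motifs(_random_dna(rng, utr_len), rng)
        chars = list(utr)
        protected: list[tuple[int, int]] = []
        if is_multi:
            hex_prox = _draw_pas_class(
                rng, config.pas_canonical_prob_proximal, config.pas_variant_prob_proximal
            )
            hex_dist = _draw_pas_class(
                rng, config.pas_canonical_prob_distal, config.pas_variant_prob_distal
            )
            span, off = _plant_site(chars, l_c, hex_prox, rng)
            if span:
                protected.append(span)
            pas_truth.append(PlantedPAS(gene_id, "proximal", hex_prox, off))
            span, off = _plant_site(chars, utr_len, hex_dist, rng)
            if span:
                protected.append(span)
            pas_truth.append(PlantedPAS(gene_id, "distal", hex_dist, off))
        else:
            hex_single = _draw_pas_class(
                rng, config.pas_canonical_prob_single, config.pas_variant_prob_single
            )
            span, off = _plant_site(chars, utr_len, hex_single, rng)
            if span:
                protected.append(span)
            pas_truth.append(PlantedPAS(gene_id, "single", hex_single, off))
        # planting can create a motif at a junction; scrub everything else
        utr = _scrub_motifs("".join(chars), rng, protected=protected)

        pad_left = _scrub_motifs(_random_dna(rng, _CONTIG_PAD), rng)
        pad_right = _scrub_motifs(_random_dna(rng, _CONTIG_PAD), rng)
        forward = pad_left + utr + pad_right
        m = len(forward)
        if strand == "+":
            contig_seq = forward
            utr_start = _CONTIG_PAD
            utr_end = _CONTIG_PAD + utr_len
            prox = utr_start + l_c
            dist = utr_end
        else:
            contig_seq = reverse_complement(forward)
            utr_start = m - (_CONTIG_PAD + utr_len)
            utr_end = m - _CONTIG_PAD
            prox = m - (_CONTIG_PAD + l_c)
            dist = utr_start
        contigs[contig] = contig_seq
        if is_multi:
            tandem.append(
                TandemUTRGene(
                    gene_id=gene_id,
                    contig=contig,
                    strand=strand,
                    utr_start=utr_start,
                    utr_end=utr_end,
                    proximal_cleavage=prox,
                    distal_cleavage=dist,
                    common_len=l_c,
                    extension_len=l_e,
                    sequence_long_utr=utr,
                )
            )
        else:
            cleavage = utr_end if strand == "+" else utr_start
            single.append(
                SingleSiteGene(gene_id, contig, strand, utr_start, utr_end, cleavage, utr)
            )
    return SimulatedAnnotation(tuple(tandem), tuple(single), contigs, tuple(pas_truth))


def generate_truth(config: SimConfig, annotation: SimulatedAnnotation) -> list[TruthRecord]:
    """Assign rhythmic flags, baselines, amplitudes and phases.

    Exactly ``round(n_multi * frac_rhythmic)`` multi-PAS genes are
    rhythmic.  Baselines are uniform on [0.2, 0.8], phases uniform on
    [0, 24); an amplitude that would push psi outside [0, 1] is shrunk
    (with a logged warning) and the trajectory additionally clamped.
    """
    rng = _rng(config, 1)
    t = config.time_grid()
    multi_ids = [g.gene_id for g in annotation.tandem_genes]
    n_rhythmic = int(round(len(multi_ids) * config.frac_rhythmic))
    rhythmic_ids = set(
        rng.choice(np.array(multi_ids), size=n_rhythmic, replace=False).tolist()
    ) if n_rhythmic else set()

    records: list[TruthRecord] = []
    for gene_id in multi_ids:
        baseline = float(rng.uniform(0.2, 0.8))
        is_rhythmic = gene_id in rhythmic_ids
        if is_rhythmic:
            amp = float(rng.uniform(*config.amplitude_range))
            max_amp = min(baseline, 1.0 - baseline)
            if amp > max_amp:
                logger.warning(
                    "%s: amplitude %.3f incompatible with baseline %.3f; shrunk to %.3f",
                    gene_id, amp, baseline, max_amp,
                )
                amp = max_amp
            phase = float(rng.uniform(0.0, 24.0))
        else:
            amp, phase = 0.0, 0.0
        psi = np.clip(
            baseline + amp * np.cos(2 * np.pi * (t - phase) / config.period_true), 0.0, 1.0
        )
        records.append(
            TruthRecord(gene_id, True, is_rhythmic, baseline, amp, phase, tuple(psi.tolist()))
        )
    for g in annotation.single_genes:
        records.append(
            TruthRecord(g.gene_id, False, False, 1.0, 0.0, 0.0, tuple([1.0] * len(t)))
        )
    records.sort(key=lambda r: r.gene_id)
    return records


def simulate_counts(
    annotation: SimulatedAnnotation, truth: Sequence[TruthRecord], config: SimConfig
) -> CountsTable:
    """Draw segment counts: n ~ Poisson(mean), c_ext ~ Binomial(n, p_ext).

    ``p_ext = theta*L_e / (L_c + theta*L_e)`` with theta the long-isoform
    fraction.  Gene-level totals for TPM are drawn independently from a
    log-normal expression profile scaled to the configured library size.
    """
    rng = _rng(config, 2)
    t = config.time_grid()
    truth_by_id = {r.gene_id: r for r in truth}
    missing = sorted(set(g for g in annotation.all_gene_ids) - set(truth_by_id))
    if missing:
        raise ValueError(f"truth table does not cover genes {missing}")

    lengths = {g.gene_id: (g.common_len, g.extension_len) for g in annotation.tandem_genes}
    for g in annotation.single_genes:
        lengths[g.gene_id] = (g.utr_len, 0)

    gene_ids = annotation.all_gene_ids
    expr_weight = np.exp(rng.normal(0.0, config.expr_sigma, size=len(gene_ids)))
    expr_mean = expr_weight / expr_weight.sum() * config.library_size

    rows = []
    for gene_id, mean_total in zip(gene_ids, expr_mean):
        rec = truth_by_id[gene_id]
        l_c, l_e = lengths[gene_id]
        theta = 1.0 - np.asarray(rec.psi_prox_by_time)
        p_ext = np.where(l_e > 0, theta * l_e / (l_c + theta * l_e), 0.0)
        n = rng.poisson(config.reads_per_gene_mean, size=len(t))
        c_ext = rng.binomial(n, p_ext)
        totals = rng.poisson(mean_total, size=len(t))
        for j, time_ct in enumerate(t):
            rows.append((gene_id, float(time_ct), int(n[j] - c_ext[j]), int(c_ext[j]), int(totals[j])))
    frame = pd.DataFrame(rows, columns=CountsTable.COLUMNS)
    return CountsTable(frame)


# ---------------------------------------------------------------------------
# dataset serialization
# ---------------------------------------------------------------------------


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in truth],
            "is_multi_pas": [r.is_multi_pas for r in truth],
            "is_rhythmic": [r.is_rhythmic for r in truth],
            "baseline_psi_prox": [r.baseline_psi_prox for r in truth],
            "amplitude": [r.amplitude for r in truth],
            "phase_true": [r.phase_true for r in truth],
            "psi_prox_by_time": [";".join(repr(v) for v in r.psi_prox_by_time) for r in truth],
        }
    )


def frame_to_truth(frame: pd.DataFrame) -> list[TruthRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            TruthRecord(
                gene_id=row.gene_id,
                is_multi_pas=bool(row.is_multi_pas),
                is_rhythmic=bool(row.is_rhythmic),
                baseline_psi_prox=float(row.baseline_psi_prox),
                amplitude=float(row.amplitude),
                phase_true=float(row.phase_true),
                psi_prox_by_time=tuple(float(v) for v in str(row.psi_prox_by_time).split(";")),
            )
        )
    return records


def read_truth(path: str | Path) -> list[TruthRecord]:
    return frame_to_truth(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_dataset(
    annotation: SimulatedAnnotation,
    truth: Sequence[TruthRecord],
    counts: CountsTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write GFF3 + FASTA + counts TSV + truth TSV; returns the paths.

    The files round-trip bit-identically through the readers in
    :mod:`circapa.annotation`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": out / "annotation.gff3",
        "fasta": out / "contigs.fa",
        "counts": out / "counts.tsv",
        "truth": out / "truth.tsv",
    }
    write_gff3(annotation.tandem_genes, annotation.single_genes, paths["gff3"])
    write_fasta(annotation.contigs, paths["fasta"])
    counts.to_tsv(paths["counts"])
    # %.17g round-trips every double exactly
    truth_to_frame(truth).to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    return paths


def simulate_dataset(config: SimConfig) -> tuple[SimulatedAnnotation, list[TruthRecord], CountsTable]:
    """Convenience wrapper: annotation + truth + counts in one call."""
    annotation = generate_annotation(config)
    truth = generate_truth(config, annotation)
    counts = simulate_counts(annotation, truth, config)
    return annotation, truth, counts
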