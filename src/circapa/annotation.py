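"""Reading, validation and writing of 3'-end annotations, sequences and counts.

Coordinate convention
---------------------
Internally every interval is 0-based, half-open on the contig, as in BED.
GFF3 input/output follows the GFF3 standard (1-based, closed intervals);
the conversion happens at the file boundary and nowhere else.

A tandem-UTR gene is modelled as a 3'UTR with two cleavage sites: the
*proximal* site terminates the short isoform at the end of the *common*
region (length ``L_c``, shared by both isoforms), the *distal* site
terminates the long isoform at the end of the *extension* region
(length ``L_e``, present only in the long isoform).  On the minus strand
the distal cleavage site has the smaller contig coordinate, but it is
always the 3'-most position in transcript orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_REVCOMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_REVCOMP)[::-1]


class MalformedAnnotationError(ValueError):
    """Raised when a GFF3 record violates the tandem-UTR layout."""


class CountsValidationError(ValueError):
    """Raised when a counts table violates the time-grid or count contracts."""


@dataclass(frozen=True)
class TandemUTRGene:
    """A gene with a proximal and a distal poly(A) site in one 3'UTR.

    ``sequence_long_utr`` is the long-isoform 3'UTR in transcript
    orientation (5'->3'), i.e. already reverse-complemented for minus
    strand genes.  ``proximal_cleavage``/``distal_cleavage`` are contig
    boundary coordinates in the 0-based half-open system.
    """

    gene_id: str
    contig: str
    strand: str
    utr_start: int
    utr_end: int
    proximal_cleavage: int
    distal_cleavage: int
    common_len: int
    extension_len: int
    sequence_long_utr: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise MalformedAnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.common_len < 1 or self.extension_len < 1:
            raise MalformedAnnotationError(
                f"{self.gene_id}: segment lengths must be >= 1 nt "
                f"(L_c={self.common_len}, L_e={self.extension_len})"
            )
        if self.strand == "-" and not self.distal_cleavage < self.proximal_cleavage:
            raise MalformedAnnotationError(
                f"{self.gene_id}: on - strand the distal site must have the "
                "lower contig coordinate"
            )

    @property
    def short_utr_len(self) -> int:
        return self.common_len

    @property
    def long_utr_len(self) -> int:
        return self.common_len + self.extension_len


@dataclass(frozen=True)
class SingleSiteGene:
    """A gene with a single annotated poly(A) site (no tandem pair)."""

    gene_id: str
    contig: str
    strand: str
    utr_start: int
    utr_end: int
    cleavage: int
    sequence_utr: str

    @property
    def utr_len(self) -> int:
        return self.utr_end - self.utr_start


class CountsTable:
    """Per-gene, per-time-point segment read counts on a shared time grid.

    Wraps a DataFrame with columns ``gene_id, time_ct, c_common, c_ext,
    gene_total_reads`` and carries the inferred time-grid metadata:
    the sampling interval and the number of circadian cycles
    (``n_cycles = floor(n_points * interval / 24)``, at least 1).
    """

    COLUMNS = ["gene_id", "time_ct", "c_common", "c_ext", "gene_total_reads"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, self.COLUMNS].copy()
        if frame.empty:
            raise CountsValidationError("counts table is empty")
        for col in ("c_common", "c_ext", "gene_total_reads"):
            if (frame[col] < 0).any():
                bad = frame.loc[frame[col] < 0, "gene_id"].unique().tolist()
                raise CountsValidationError(f"negative {col} for genes {bad}")
        # normalize row order first: the table contract is order-free
        frame = frame.sort_values(["gene_id", "time_ct"], kind="mergesort").reset_index(drop=True)
        grids = frame.groupby("gene_id", sort=True)["time_ct"].apply(tuple)
        ref = grids.iloc[0]
        ragged = grids[grids != ref].index.tolist()
        if ragged:
            raise CountsValidationError(f"ragged time grids for genes {ragged}")
        grid = np.asarray(ref, dtype=float)
        if len(grid) < 2 or not np.all(np.diff(grid) > 0):
            raise CountsValidationError("time grid must be strictly increasing with >= 2 points")
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0]):
            raise CountsValidationError("time grid must be uniformly spaced")
        self.frame = frame
        self.time_grid = grid
        self.interval = float(steps[0])
        span = len(grid) * self.interval
        self.n_cycles = max(1, int(math.floor(span / 24.0)))

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.frame["gene_id"].unique().tolist())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountsTable":
        path = Path(path)
        try:
            frame = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError as exc:
            raise CountsValidationError(f"{path}: empty counts file") from exc
        missing = set(cls.COLUMNS) - set(frame.columns)
        if missing:
            raise CountsValidationError(f"{path}: missing columns {sorted(missing)}")
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_counts(tsv_path: str | Path) -> CountsTable:
    """Read and validate a segment-counts TSV (see :class:`CountsTable`)."""
    return CountsTable.from_tsv(tsv_path)


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------

_SEGMENT_TYPE = "three_prime_UTR_segment"


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(
    tandem: Sequence[TandemUTRGene],
    single: Sequence[SingleSiteGene],
    path: str | Path,
) -> None:
    """Write the 3'-end annotation layout consumed by the readers.

    One ``gene`` feature per gene; child ``three_prime_UTR_segment``
    features carry ``segment=common|extension`` and ``site=proximal|distal``
    attributes.  Coordinates are converted to 1-based closed intervals.
    """

    def line(contig, ftype, start0, end0, strand, attrs):
        attr = ";".join(f"{k}={v}" for k, v in attrs)
        return f"{contig}\tcircapa\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(tandem, key=lambda g: g.gene_id):
            fh.write(line(g.contig, "gene", g.utr_start, g.utr_end, g.strand, [("ID", g.gene_id)]))
            if g.strand == "+":
                common = (g.utr_start, g.proximal_cleavage)
                ext = (g.proximal_cleavage, g.utr_end)
            else:
                common = (g.proximal_cleavage, g.utr_end)
                ext = (g.utr_start, g.proximal_cleavage)
            fh.write(
                line(
                    g.contig,
                    _SEGMENT_TYPE,
                    *common,
                    g.strand,
                    [("ID", f"{g.gene_id}:common"), ("Parent", g.gene_id), ("segment", "common"), ("site", "proximal")],
                )
            )
            fh.write(
                line(
                    g.contig,
                    _SEGMENT_TYPE,
                    *ext,
                    g.strand,
                    [("ID", f"{g.gene_id}:extension"), ("Parent", g.gene_id), ("segment", "extension"), ("site", "distal")],
                )
            )
        for g in sorted(single, key=lambda g: g.gene_id):
            fh.write(line(g.contig, "gene", g.utr_start, g.utr_end, g.strand, [("ID", g.gene_id)]))
            fh.write(
                line(
                    g.contig,
                    _SEGMENT_TYPE,
                    g.utr_start,
                    g.utr_end,
                    g.strand,
                    [("ID", f"{g.gene_id}:common"), ("Parent", g.gene_id), ("segment", "common"), ("site", "proximal")],
                )
            )


def read_three_prime_annotation(
    gff3_path: str | Path, fasta_path: str | Path
) -> tuple[list[TandemUTRGene], list[SingleSiteGene]]:
    """Read a 3'-end annotation, returning (tandem genes, single-site genes).

    Coordinates are converted from GFF3 1-based closed to 0-based
    half-open.  Minus-strand sequences are reverse complemented so the
    returned sequence is always the transcript 5'->3' orientation.  Genes
    with more than one extension segment are collapsed onto the pair of
    sites flanking the longest extension (the downstream analysis only
    considers the top-two isoform pair) and a warning is logged.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    tandem: list[TandemUTRGene] = []
    single: list[SingleSiteGene] = []
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.id
        if gene.seqid not in fasta:
            raise MalformedAnnotationError(f"{gene_id}: contig {gene.seqid!r} missing from FASTA")
        contig_seq = str(fasta[gene.seqid][:])
        strand = gene.strand
        segs = list(db.children(gene, featuretype=_SEGMENT_TYPE))
        commons = [s for s in segs if s.attributes.get("segment", [""])[0] == "common"]
        exts = [s for s in segs if s.attributes.get("segment", [""])[0] == "extension"]
        if len(commons) != 1:
            raise MalformedAnnotationError(f"{gene_id}: expected exactly one common segment")
        common = commons[0]
        c_start, c_end = common.start - 1, common.end

        if not exts:
            utr_start, utr_end = c_start, c_end
            seq = contig_seq[utr_start:utr_end]
            if strand == "-":
                seq = reverse_complement(seq)
            cleavage = utr_end if strand == "+" else utr_start
            single.append(
                SingleSiteGene(gene_id, gene.seqid, strand, utr_start, utr_end, cleavage, seq)
            )
            continue

        if len(exts) > 1:
            logger.warning(
                "%s: %d extension segments; collapsing to the longest", gene_id, len(exts)
            )
        ext = max(exts, key=lambda s: s.end - s.start + 1)
        e_start, e_end = ext.start - 1, ext.end

        if strand == "+":
            if e_start < c_end:
                raise MalformedAnnotationError(
                    f"{gene_id}: extension segment upstream of common segment"
                )
            utr_start, utr_end = c_start, e_end
            proximal, distal = e_start, e_end
            common_len = e_start - c_start
            seq = contig_seq[utr_start:utr_end]
        else:
            if e_end > c_start:
                raise MalformedAnnotationError(
                    f"{gene_id}: extension segment upstream of common segment"
                )
            utr_start, utr_end = e_start, c_end
            proximal, distal = e_end, e_start
            common_len = c_end - e_end
            seq = reverse_complement(contig_seq[utr_start:utr_end])
        extension_len = e_end - e_start
        # Collapse rule: the common region runs from the transcript 5' start
        # of the UTR to the start of the chosen extension.
        tandem.append(
            TandemUTRGene(
                gene_id=gene_id,
                contig=gene.seqid,
                strand=strand,
                utr_start=utr_start,
                utr_end=utr_end,
                proximal_cleavage=proximal,
                distal_cleavage=distal,
                common_len=common_len,
                extension_len=extension_len,
                sequence_long_utr=seq[: common_len + extension_len],
            )
        )
    tandem.sort(key=lambda g: g.gene_id)
    single.sort(key=lambda g: g.gene_id)
    return tandem, single


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------


def compute_tpm(
    counts: CountsTable,
    genes: Iterable[TandemUTRGene | SingleSiteGene] | Mapping[str, int],
) -> pd.DataFrame:
    """Length-normalized expression: tpm = 1e6 * (c/L) / sum_genes(c/L).

    ``c`` is ``gene_total_reads`` and ``L`` the long-isoform UTR length
    (the UTR length for single-site genes); any fixed per-gene length
    yields the same ordering under a TPM threshold, see the methods note.
    Returns a DataFrame with columns ``gene_id, time_ct, tpm``.
    """
    if isinstance(genes, Mapping):
        lengths = dict(genes)
    else:
        lengths = {}
        for g in genes:
            lengths[g.gene_id] = g.long_utr_len if isinstance(g, TandemUTRGene) else g.utr_len
    frame = counts.frame.copy()
    missing = sorted(set(frame["gene_id"]) - set(lengths))
    if missing:
        raise KeyError(f"genes without an annotated length: {missing}")
    frame["length"] = frame["gene_id"].map(lengths)
    frame["rate"] = frame["gene_total_reads"] / frame["length"]
    denom = frame.groupby("time_ct")["rate"].transform("sum")
    if (denom == 0).any():
        bad = sorted(frame.loc[denom == 0, "time_ct"].unique().tolist())
        raise ZeroDivisionError(f"zero total library at time points {bad}")
    frame["tpm"] = 1e6 * frame["rate"] / denom
    return frame[["gene_id", "time_ct", "tpm"]]
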