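"""Filtering cascade, top-two isoform selection, and the APA index.

The cascade removes, in order:

1. genes with fewer than 20 reads in their 3'UTR (by default at *every*
   time point, so that psi is estimable everywhere; a pooled mode sums
   over time points instead);
2. isoforms whose mean psi over all time points is < 0.1;
3. isoforms whose psi is 0 at >= 2 time points (two-cycle designs) or
   >= 1 time point (one-cycle designs) — psi = 0 is an exact event here,
   arising only from zero extension reads or boundary clamping;
4. genes whose mean TPM over all time points is < 1 (applied at gene
   level: isoform-level TPM is not computable from segment counts).

A gene survives only if both isoforms of its pair survive.  The APA
index of a surviving pair is ``psi_proximal - psi_distal`` at each time
point: positive values mean proximal (short-isoform) dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CountsTable
from .psi import PsiMatrix


@dataclass
class FilterReport:
    """Per-stage survivor bookkeeping; stages are monotone by construction."""

    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, survivors_in, survivors_out, removed: dict | list) -> None:
        self.stages.append(
            {
                "name": name,
                "n_in": len(survivors_in),
                "n_out": len(survivors_out),
                "removed": sorted(removed) if isinstance(removed, (set, list)) else removed,
            }
        )

    def survivors_per_stage(self) -> list[tuple[str, int]]:
        return [(s["name"], s["n_out"]) for s in self.stages]

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def filter_low_coverage(
    counts: CountsTable,
    min_reads: int = 20,
    mode: str = "per_timepoint",
    report: FilterReport | None = None,
) -> tuple[list[str], FilterReport]:
    """Keep genes with >= ``min_reads`` 3'UTR reads (c_common + c_ext).

    ``mode='per_timepoint'`` requires the threshold at every time point;
    ``mode='pooled'`` sums across time points.
    """
    if mode not in ("per_timepoint", "pooled"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    report = report or FilterReport()
    frame = counts.frame
    total = frame["c_common"] + frame["c_ext"]
    per_gene = total.groupby(frame["gene_id"], sort=True)
    if mode == "per_timepoint":
        ok = per_gene.min() >= min_reads
    else:
        ok = per_gene.sum() >= min_reads
    survivors = sorted(ok[ok].index.tolist())
    removed = sorted(ok[~ok].index.tolist())
    report.add_stage(f"coverage(>={min_reads} reads, {mode})", ok.index, survivors, removed)
    return survivors, report


def filter_isoforms(
    psi: PsiMatrix,
    tpm: pd.DataFrame,
    n_cycles: int,
    min_mean_psi: float = 0.1,
    min_mean_tpm: float = 1.0,
    genes: list[str] | None = None,
    report: FilterReport | None = None,
) -> tuple[list[str], FilterReport]:
    """Apply the mean-psi, zero-time-point and TPM rules.

    ``genes`` restricts the input set (survivors of the coverage stage);
    the returned genes are those for which *both* isoforms pass the
    isoform-level rules and the gene passes the TPM rule.
    """
    if n_cycles not in (1, 2):
        raise ValueError(f"n_cycles must be 1 or 2, got {n_cycles}")
    zero_limit = 2 if n_cycles == 2 else 1
    report = report or FilterReport()

    frame = psi.frame
    if genes is not None:
        frame = frame[frame["gene_id"].isin(set(genes))]
        current = sorted(set(genes) & set(frame["gene_id"].unique()))
    else:
        current = sorted(frame["gene_id"].unique().tolist())

    g = frame[frame["gene_id"].isin(current)].groupby("gene_id", sort=True)
    mean_prox = g["psi_prox"].mean()
    mean_dist = g["psi_dist"].mean()
    psi_ok = (mean_prox >= min_mean_psi) & (mean_dist >= min_mean_psi)
    survivors = sorted(psi_ok[psi_ok].index.tolist())
    report.add_stage(
        f"mean_psi(>= {min_mean_psi} both isoforms)",
        current,
        survivors,
        sorted(set(current) - set(survivors)),
    )
    current = survivors

    sub = frame[frame["gene_id"].isin(current)]
    gz = sub.groupby("gene_id", sort=True)
    zeros_prox = gz["psi_prox"].apply(lambda s: int((s == 0.0).sum()))
    zeros_dist = gz["psi_dist"].apply(lambda s: int((s == 0.0).sum()))
    zero_ok = (zeros_prox < zero_limit) & (zeros_dist < zero_limit)
    survivors = sorted(zero_ok[zero_ok].index.tolist())
    report.add_stage(
        f"zero_timepoints(< {zero_limit} zeros per isoform, n_cycles={n_cycles})",
        current,
        survivors,
        sorted(set(current) - set(survivors)),
    )
    current = survivors

    mean_tpm = tpm.groupby("gene_id", sort=True)["tpm"].mean()
    tpm_ok_ids = set(mean_tpm[mean_tpm >= min_mean_tpm].index)
    survivors = sorted(set(current) & tpm_ok_ids)
    report.add_stage(
        f"mean_tpm(>= {min_mean_tpm})",
        current,
        survivors,
        sorted(set(current) - set(survivors)),
    )
    return survivors, report


def select_top_two(mean_psi: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Select the pair(s) of isoforms with the two highest mean psi values.

    ``mean_psi`` has columns ``gene_id, isoform_id, mean_psi``.  The
    top isoform is the one with the highest mean (ties broken by
    isoform_id); every isoform tied at the second-highest value forms an
    independent pair with the top isoform, each with a distinct
    ``pair_id``.  Genes with fewer than two isoforms are dropped and
    returned separately.

    Returns ``(pairs, dropped)`` where ``pairs`` has columns ``gene_id,
    pair_id, isoform_top, isoform_second``.
    """
    rows = []
    dropped: list[str] = []
    for gene_id, grp in mean_psi.groupby("gene_id", sort=True):
        grp = grp.sort_values(["mean_psi", "isoform_id"], ascending=[False, True], kind="mergesort")
        if len(grp) < 2:
            dropped.append(gene_id)
            continue
        top = grp.iloc[0]
        rest = grp.iloc[1:]
        second_value = rest["mean_psi"].max()
        seconds = rest[rest["mean_psi"] == second_value]
        for k, (_, iso) in enumerate(seconds.iterrows()):
            rows.append(
                {
                    "gene_id": gene_id,
                    "pair_id": f"{gene_id}|{k}",
                    "isoform_top": top["isoform_id"],
                    "isoform_second": iso["isoform_id"],
                }
            )
    pairs = pd.DataFrame(rows, columns=["gene_id", "pair_id", "isoform_top", "isoform_second"])
    return pairs, dropped


def top_two_from_psi_matrix(psi: PsiMatrix, genes: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Top-two selection for the two-isoform (proximal/distal) pipeline."""
    means = psi.mean_psi()
    means = means[means["gene_id"].isin(set(genes))]
    long = pd.concat(
        [
            means.assign(isoform_id="proximal", mean_psi=means["mean_psi_prox"]),
            means.assign(isoform_id="distal", mean_psi=means["mean_psi_dist"]),
        ]
    )[["gene_id", "isoform_id", "mean_psi"]]
    return select_top_two(long)


def compute_apa_index(psi: PsiMatrix, pairs: pd.DataFrame) -> pd.DataFrame:
    """APA index time series per surviving pair.

    ``apa_index(t) = psi_prox(t) - psi_dist(t)``; missing time points
    are excluded pairwise (they surface as NaN rows).  Returns columns
    ``gene_id, pair_id, time_ct, apa_index, mean_apa_index``.
    """
    pair_ids = pairs[["gene_id", "pair_id"]].drop_duplicates()
    sub = psi.frame.merge(pair_ids, on="gene_id", how="inner")
    sub["apa_index"] = sub["psi_prox"] - sub["psi_dist"]
    means = sub.groupby("pair_id", sort=True)["apa_index"].mean().rename("mean_apa_index")
    out = sub.merge(means, on="pair_id")
    out = out[["gene_id", "pair_id", "time_ct", "apa_index", "mean_apa_index"]]
    return out.sort_values(["pair_id", "time_ct"], kind="mergesort").reset_index(drop=True)
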