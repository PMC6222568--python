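"""Characterization of poly(A) signals, 3'UTR lengths and APA-index
distributions for all vs. rhythmic tandem-UTR pairs.

The poly(A) signal (PAS) scanner searches the 40 nt of transcript
sequence immediately 5' of a cleavage site for the canonical hexamer
AAUAAA and configured variants (default: AUUAAA), with U/T equivalence.
Classification priority is canonical > variant > none; within the
winning class the occurrence closest to the 3' end is reported.  When
the proximal and distal cleavage sites lie within 40 nt of one another,
a motif falling in both windows is counted for both sites
(``double_counted``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SingleSiteGene, TandemUTRGene

CANONICAL = "AATAAA"
DEFAULT_VARIANTS = ("ATTAAA",)
PAS_WINDOW = 40

_CLASS_RANK = {"canonical": 0, "variant": 1, "none": 2}


@dataclass(frozen=True)
class PASClassification:
    """PAS call for one cleavage site.

    ``offset_from_3end`` counts the nucleotides between the hexamer's
    last base and the cleavage site (0 = flush against the 3' end).
    """

    gene_id: str
    site: str
    pas_class: str
    hexamer: str | None
    offset_from_3end: int | None
    truncated: bool = False
    double_counted: bool = False


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_pas(
    sequence: str,
    cleavage_offset: int,
    window: int = PAS_WINDOW,
    variants: Sequence[str] = DEFAULT_VARIANTS,
    gene_id: str = "",
    site: str = "",
) -> PASClassification:
    """Scan the window [cleavage_offset - window, cleavage_offset).

    ``sequence`` must be in transcript orientation (RNA or DNA alphabet).
    If the window extends past the sequence start the scan is truncated
    and flagged.
    """
    seq = _normalize(sequence)
    if not 0 < cleavage_offset <= len(seq):
        raise ValueError(f"cleavage offset {cleavage_offset} outside sequence of length {len(seq)}")
    win_start = cleavage_offset - window
    truncated = win_start < 0
    win_start = max(win_start, 0)
    region = seq[win_start:cleavage_offset]

    for pas_class, motifs in (("canonical", [CANONICAL]), ("variant", [_normalize(v) for v in variants])):
        best_pos, best_motif = -1, None
        for motif in motifs:
            pos = region.rfind(motif)
            if pos > best_pos:
                best_pos, best_motif = pos, motif
        if best_pos >= 0:
            offset = len(region) - (best_pos + len(best_motif))
            return PASClassification(
                gene_id, site, pas_class, best_motif, offset, truncated, False
            )
    return PASClassification(gene_id, site, "none", None, None, truncated, False)


def apply_double_count_rule(
    proximal: PASClassification,
    distal: PASClassification,
    site_distance_nt: int,
    window: int = PAS_WINDOW,
) -> tuple[PASClassification, PASClassification]:
    """Share a motif between overlapping scan windows of nearby sites.

    When the two cleavage sites are < ``window`` nt apart, a hexamer in
    the shared region is counted for both sites; both calls are then
    flagged ``double_counted``.  A shared motif only replaces a call of
    strictly lower priority.
    """
    if site_distance_nt < 0:
        raise ValueError("site distance must be >= 0")
    if site_distance_nt >= window:
        return proximal, distal
    prox, dist = proximal, distal
    hex_len = 6

    # both scans resolved to the same occurrence -> count it twice
    if (
        prox.pas_class != "none"
        and dist.pas_class != "none"
        and dist.hexamer == prox.hexamer
        and dist.offset_from_3end == prox.offset_from_3end + site_distance_nt
    ):
        return replace(prox, double_counted=True), replace(dist, double_counted=True)

    # a proximal-window motif inside the distal window outranks the distal call
    if prox.pas_class != "none":
        offset_in_distal = prox.offset_from_3end + site_distance_nt
        if (
            offset_in_distal + hex_len <= window
            and _CLASS_RANK[prox.pas_class] < _CLASS_RANK[dist.pas_class]
        ):
            dist = replace(
                prox, site=distal.site, offset_from_3end=offset_in_distal, double_counted=True
            )
            prox = replace(prox, double_counted=True)
    # a distal-window motif upstream of the proximal cleavage outranks the
    # proximal call
    if distal.pas_class != "none":
        offset_in_prox = distal.offset_from_3end - site_distance_nt
        if offset_in_prox >= 0 and _CLASS_RANK[distal.pas_class] < _CLASS_RANK[prox.pas_class]:
            prox = replace(
                distal, site=proximal.site, offset_from_3end=offset_in_prox, double_counted=True
            )
            dist = replace(dist, double_counted=True)
    return prox, dist


def classify_pas_combination(proximal_class: str, distal_class: str) -> tuple[str, str]:
    """(proximal, distal) class pair -> ('variant-canonical', 'noncanonical-canonical')."""
    for c in (proximal_class, distal_class):
        if c not in _CLASS_RANK:
            raise ValueError(f"unknown PAS class {c!r}")
    fine = f"{proximal_class}-{distal_class}"
    agg = "-".join(
        "canonical" if c == "canonical" else "noncanonical" for c in (proximal_class, distal_class)
    )
    return fine, agg


def classify_gene_sites(
    gene: TandemUTRGene,
    window: int = PAS_WINDOW,
    variants: Sequence[str] = DEFAULT_VARIANTS,
) -> tuple[PASClassification, PASClassification]:
    """Scan both cleavage sites of a tandem gene and apply the shared-window rule."""
    seq = gene.sequence_long_utr
    prox = scan_pas(seq, gene.common_len, window, variants, gene.gene_id, "proximal")
    dist = scan_pas(seq, gene.long_utr_len, window, variants, gene.gene_id, "distal")
    return apply_double_count_rule(prox, dist, gene.extension_len, window)


def classify_all_sites(
    genes: Iterable[TandemUTRGene],
    window: int = PAS_WINDOW,
    variants: Sequence[str] = DEFAULT_VARIANTS,
) -> pd.DataFrame:
    """Site classifications for a gene collection, one row per gene."""
    rows = []
    for g in genes:
        prox, dist = classify_gene_sites(g, window, variants)
        fine, agg = classify_pas_combination(prox.pas_class, dist.pas_class)
        rows.append(
            {
                "gene_id": g.gene_id,
                "proximal_class": prox.pas_class,
                "proximal_hexamer": prox.hexamer,
                "proximal_offset": prox.offset_from_3end,
                "distal_class": dist.pas_class,
                "distal_hexamer": dist.hexamer,
                "distal_offset": dist.offset_from_3end,
                "double_counted": prox.double_counted or dist.double_counted,
                "combination": fine,
                "combination_2x2": agg,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float

    @property
    def delta_median(self) -> float:
        return self.median_a - self.median_b


def compare_groups(values_a, values_b, method: str = "auto") -> RankSumResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum comparison.

    Small tie-free samples use the exact null distribution; larger or
    tied samples fall back to the tie-corrected, continuity-corrected
    normal approximation (the usual automatic switch — the pure normal
    approximation misclassifies borderline cases at tiny n, e.g. group
    sizes 3 vs 6 at U = 1).  The reported U statistic counts wins of
    group a.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return RankSumResult(float(res.statistic), float(res.pvalue), float(np.median(a)), float(np.median(b)))


def summarize_dataset(n_single: int, n_multi: int) -> dict:
    """Per-dataset summary: gene count, % multi-PAS, mean sites per gene."""
    n = n_single + n_multi
    if n == 0:
        raise ValueError("empty dataset")
    return {
        "n_genes": n,
        "n_single_pas": n_single,
        "n_multi_pas": n_multi,
        "pct_multi_pas": 100.0 * n_multi / n,
        "mean_sites_per_gene": (n_single + 2 * n_multi) / n,
    }


def count_overlap(pair_sets: Mapping[str, set] | Sequence[set]) -> dict:
    """Overlap counts across >= 2 runs.

    Pair identity requires *both* isoforms of the pair to match, so
    elements should encode the full pair (e.g. ``(gene_id, isoform_top,
    isoform_second)``).  Returns per-run sizes, all pairwise overlaps,
    and the intersection of all runs.
    """
    if not isinstance(pair_sets, Mapping):
        pair_sets = {f"run{i}": s for i, s in enumerate(pair_sets)}
    names = sorted(pair_sets)
    if len(names) < 2:
        raise ValueError("need at least two runs to count overlaps")
    out = {"sizes": {k: len(pair_sets[k]) for k in names}, "pairwise": {}, "all": 0}
    for i, ki in enumerate(names):
        for kj in names[i + 1 :]:
            out["pairwise"][f"{ki}&{kj}"] = len(pair_sets[ki] & pair_sets[kj])
    inter = set.intersection(*(set(pair_sets[k]) for k in names))
    out["all"] = len(inter)
    return out


def _median_or_none(values) -> float | None:
    values = np.asarray(values, dtype=float)
    return float(np.median(values)) if values.size else None


def _ranksum_or_none(a, b) -> dict | None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    r = compare_groups(a, b)
    return {
        "u_statistic": r.u_statistic,
        "p_value": r.p_value,
        "median_a": r.median_a,
        "median_b": r.median_b,
    }


def phase_histogram(phases, period: float = 24.0, bin_width: float = 2.0) -> list[int]:
    """Counts of acrophases in ``period/bin_width`` bins of ``bin_width`` h."""
    edges = np.arange(0.0, period + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.asarray(phases, dtype=float) % period, bins=edges)
    return counts.astype(int).tolist()


def characterization_report(
    tandem_genes: Sequence[TandemUTRGene],
    single_genes: Sequence[SingleSiteGene],
    pairs: pd.DataFrame,
    psi_means: pd.DataFrame,
    apa_index: pd.DataFrame,
    rhythm: pd.DataFrame,
    window: int = PAS_WINDOW,
    variants: Sequence[str] = DEFAULT_VARIANTS,
) -> dict:
    """Assemble the full characterization report.

    Compares the all-pairs set against the rhythmic subset: 3'UTR
    lengths (short, long, difference), mean-psi by PAS class (canonical
    vs others, pooling both sites) and by site (proximal vs distal, with
    the distal-minus-proximal median difference), mean APA index, the
    PAS combination table, the acrophase histogram in 2-h bins, and the
    dataset summary.  Every two-group contrast carries a
    Mann-Whitney-Wilcoxon test.
    """
    genes_by_id = {g.gene_id: g for g in tandem_genes}
    pas = classify_all_sites(
        [genes_by_id[g] for g in pairs["gene_id"] if g in genes_by_id], window, variants
    )

    merged = pairs.merge(psi_means, on="gene_id").merge(pas, on="gene_id")
    apa_means = apa_index[["pair_id", "mean_apa_index"]].drop_duplicates()
    merged = merged.merge(apa_means, on="pair_id", how="left")
    merged = merged.merge(rhythm[["pair_id", "rhythmic", "phase_ct"]], on="pair_id", how="left")
    merged["rhythmic"] = merged["rhythmic"].fillna(False).astype(bool)
    merged["short_len"] = merged["gene_id"].map(lambda g: genes_by_id[g].short_utr_len)
    merged["long_len"] = merged["gene_id"].map(lambda g: genes_by_id[g].long_utr_len)
    merged["len_diff"] = merged["long_len"] - merged["short_len"]

    rhythmic = merged[merged["rhythmic"]]
    has_rhythmic = not rhythmic.empty

    def length_block(sub: pd.DataFrame) -> dict:
        return {
            "median_short_utr_nt": _median_or_none(sub["short_len"]),
            "median_long_utr_nt": _median_or_none(sub["long_len"]),
            "median_length_difference_nt": _median_or_none(sub["len_diff"]),
        }

    # per-isoform long table: one row per (pair, site) with PAS class + mean psi
    def isoform_table(sub: pd.DataFrame) -> pd.DataFrame:
        prox = sub[["pair_id", "proximal_class", "mean_psi_prox"]].rename(
            columns={"proximal_class": "pas_class", "mean_psi_prox": "mean_psi"}
        ).assign(site="proximal")
        dist = sub[["pair_id", "distal_class", "mean_psi_dist"]].rename(
            columns={"distal_class": "pas_class", "mean_psi_dist": "mean_psi"}
        ).assign(site="distal")
        return pd.concat([prox, dist], ignore_index=True)

    def strength_block(sub: pd.DataFrame) -> dict:
        iso = isoform_table(sub)
        canon = iso.loc[iso["pas_class"] == "canonical", "mean_psi"]
        other = iso.loc[iso["pas_class"] != "canonical", "mean_psi"]
        prox = iso.loc[iso["site"] == "proximal", "mean_psi"]
        dist = iso.loc[iso["site"] == "distal", "mean_psi"]
        block = {
            "median_psi_canonical": _median_or_none(canon),
            "median_psi_other": _median_or_none(other),
            "canonical_vs_other": _ranksum_or_none(canon, other),
            "median_psi_proximal": _median_or_none(prox),
            "median_psi_distal": _median_or_none(dist),
            "proximal_vs_distal": _ranksum_or_none(prox, dist),
        }
        if block["median_psi_distal"] is not None and block["median_psi_proximal"] is not None:
            block["delta_median_psi_distal_minus_proximal"] = (
                block["median_psi_distal"] - block["median_psi_proximal"]
            )
        return block

    def combination_block(sub: pd.DataFrame) -> dict:
        n = len(sub)
        counts = sub["combination"].value_counts().to_dict()
        counts22 = sub["combination_2x2"].value_counts().to_dict()
        return {
            "n": n,
            "counts": {k: int(v) for k, v in sorted(counts.items())},
            "fractions": {k: v / n for k, v in sorted(counts.items())} if n else {},
            "counts_2x2": {k: int(v) for k, v in sorted(counts22.items())},
            "fractions_2x2": {k: v / n for k, v in sorted(counts22.items())} if n else {},
            "pct_double_counted": 100.0 * float(sub["double_counted"].mean()) if n else None,
        }

    report = {
        "summary": summarize_dataset(len(single_genes), len(tandem_genes)),
        "n_pairs": int(len(merged)),
        "n_rhythmic_pairs": int(len(rhythmic)),
        "utr_lengths": {
            "all": length_block(merged),
            "rhythmic": length_block(rhythmic) if has_rhythmic else None,
            "difference_all_vs_rhythmic": (
                _ranksum_or_none(rhythmic["len_diff"], merged["len_diff"]) if has_rhythmic else None
            ),
            "long_all_vs_rhythmic": (
                _ranksum_or_none(rhythmic["long_len"], merged["long_len"]) if has_rhythmic else None
            ),
        },
        "site_strength": {
            "all": strength_block(merged),
            "rhythmic": strength_block(rhythmic) if has_rhythmic else None,
        },
        "apa_index": {
            "median_all": _median_or_none(merged["mean_apa_index"].dropna()),
            "median_rhythmic": (
                _median_or_none(rhythmic["mean_apa_index"].dropna()) if has_rhythmic else None
            ),
            "rhythmic_vs_all": (
                _ranksum_or_none(
                    rhythmic["mean_apa_index"].dropna(), merged["mean_apa_index"].dropna()
                )
                if has_rhythmic
                else None
            ),
        },
        "pas_combinations": {
            "all": combination_block(merged),
            "rhythmic": combination_block(rhythmic) if has_rhythmic else None,
        },
        "phase_histogram_2h": (
            phase_histogram(rhythmic["phase_ct"].dropna()) if has_rhythmic else None
        ),
    }
    return report
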