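"""Isoform-usage (psi) estimation for tandem proximal/distal 3'UTR pairs.

For a gene whose short isoform ends at the proximal site (UTR length
``L_c``) and whose long isoform extends by ``L_e`` nt to the distal
site, reads sampled uniformly from the expressed isoform mixture fall in
the extension segment with probability

    p_ext(theta) = theta * L_e / (L_c + theta * L_e),

where ``theta`` is the long-isoform (distal) usage fraction.  With
``n = c_common + c_ext`` reads and observed extension fraction
``f = c_ext / n``, the binomial likelihood Binomial(n, p_ext(theta)) is
maximized in closed form by

    theta_hat = f * L_c / (L_e * (1 - f)),

clamped to [0, 1].  ``psi_dist = theta_hat`` and
``psi_prox = 1 - theta_hat`` therefore sum to one exactly.  A grid-search
maximizer of the same likelihood is provided as an independent oracle
for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import CountsTable, TandemUTRGene


@dataclass(frozen=True)
class PsiPair:
    """Point estimates of proximal/distal usage at one time point.

    ``psi_prox``/``psi_dist`` are NaN when no reads were observed
    (``missing`` is then True); the filtering stage consumes the flag
    rather than an exception.
    """

    psi_prox: float
    psi_dist: float
    n_reads: int
    clamped: bool
    gene_id: str | None = None
    time_ct: float | None = None

    @property
    def missing(self) -> bool:
        return math.isnan(self.psi_prox)


def _check_lengths(l_c: int, l_e: int) -> None:
    if l_c < 1 or l_e < 1:
        raise ValueError(f"segment lengths must be >= 1 nt (L_c={l_c}, L_e={l_e})")


def estimate_psi_closed_form(
    c_common: int,
    c_ext: int,
    l_c: int,
    l_e: int,
    gene_id: str | None = None,
    time_ct: float | None = None,
) -> PsiPair:
    """Maximum-likelihood psi for one time point, in closed form.

    Zero total reads yields a missing-value result (NaN psi), not an
    exception.  ``clamped`` is set when the unconstrained maximizer lay
    outside [0, 1] (including the f = 1 boundary).
    """
    _check_lengths(l_c, l_e)
    if c_common < 0 or c_ext < 0:
        raise ValueError("counts must be non-negative")
    n = c_common + c_ext
    if n == 0:
        return PsiPair(float("nan"), float("nan"), 0, False, gene_id, time_ct)
    f = c_ext / n
    if f >= 1.0:
        theta, clamped = 1.0, True
    else:
        theta_raw = f * l_c / (l_e * (1.0 - f))
        clamped = theta_raw > 1.0
        theta = min(theta_raw, 1.0)
    return PsiPair(1.0 - theta, theta, n, clamped, gene_id, time_ct)


def estimate_psi_grid_oracle(
    c_common: int,
    c_ext: int,
    l_c: int,
    l_e: int,
    grid_step: float = 1e-4,
    gene_id: str | None = None,
    time_ct: float | None = None,
) -> PsiPair:
    """Exhaustive maximization of the binomial log-likelihood on a theta grid.

    Test-only oracle; independent of the closed form.  Ties resolve to
    the smallest grid value (the likelihood is unimodal, so ties only
    arise on flat boundaries).
    """
    if grid_step > 1e-3:
        raise ValueError("grid_step must be <= 1e-3")
    _check_lengths(l_c, l_e)
    n = c_common + c_ext
    if n == 0:
        return PsiPair(float("nan"), float("nan"), 0, False, gene_id, time_ct)
    theta = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    p = theta * l_e / (l_c + theta * l_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = np.where(
            c_ext > 0, c_ext * np.log(p), 0.0
        ) + np.where(c_common > 0, c_common * np.log1p(-p), 0.0)
    loglik[np.isnan(loglik)] = -np.inf
    best = float(theta[int(np.argmax(loglik))])
    clamped = best in (0.0, 1.0) and (c_ext == 0 or c_common == 0)
    return PsiPair(1.0 - best, best, n, clamped, gene_id, time_ct)


@dataclass
class PsiMatrix:
    """Per-gene, per-time-point psi estimates over a shared time grid.

    ``frame`` has columns ``gene_id, time_ct, psi_prox, psi_dist,
    n_reads, clamped`` (psi columns NaN at zero-read time points).
    """

    frame: pd.DataFrame
    time_grid: np.ndarray

    def mean_psi(self) -> pd.DataFrame:
        """Arithmetic per-gene means over time, ignoring missing values.

        Returns columns ``gene_id, mean_psi_prox, mean_psi_dist,
        n_missing``.
        """
        g = self.frame.groupby("gene_id", sort=True)
        out = g.agg(
            mean_psi_prox=("psi_prox", "mean"),
            mean_psi_dist=("psi_dist", "mean"),
            n_missing=("psi_prox", lambda s: int(s.isna().sum())),
        ).reset_index()
        return out

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PsiMatrix":
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        grid = np.sort(frame["time_ct"].unique())
        return cls(frame, grid)


def estimate_psi_series(
    counts: CountsTable, genes: Iterable[TandemUTRGene]
) -> PsiMatrix:
    """Closed-form psi for every gene and time point in a counts table.

    Every counted gene must be annotated; unknown genes raise with the
    offending ids.  Output order is (gene_id, time_ct), independent of
    input row order.
    """
    lengths = {g.gene_id: (g.common_len, g.extension_len) for g in genes}
    counted = set(counts.frame["gene_id"])
    unknown = sorted(counted - set(lengths))
    if unknown:
        raise KeyError(f"genes present in counts but not in annotation: {unknown}")

    frame = counts.frame.loc[counts.frame["gene_id"].isin(lengths)].copy()
    l_c = frame["gene_id"].map(lambda g: lengths[g][0]).to_numpy(dtype=float)
    l_e = frame["gene_id"].map(lambda g: lengths[g][1]).to_numpy(dtype=float)
    c_common = frame["c_common"].to_numpy(dtype=float)
    c_ext = frame["c_ext"].to_numpy(dtype=float)
    n = c_common + c_ext

    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(n > 0, c_ext / n, np.nan)
        theta_raw = np.where(f < 1.0, f * l_c / (l_e * (1.0 - f)), np.inf)
    theta = np.minimum(theta_raw, 1.0)
    clamped = (theta_raw > 1.0) | (f >= 1.0)
    theta = np.where(n > 0, theta, np.nan)

    out = pd.DataFrame(
        {
            "gene_id": frame["gene_id"].to_numpy(),
            "time_ct": frame["time_ct"].to_numpy(dtype=float),
            "psi_prox": 1.0 - theta,
            "psi_dist": theta,
            "n_reads": n.astype(int),
            "clamped": np.where(n > 0, clamped, False),
        }
    )
    out = out.sort_values(["gene_id", "time_ct"], kind="mergesort").reset_index(drop=True)
    return PsiMatrix(out, counts.time_grid.copy())
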