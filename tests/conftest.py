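"""Shared fixtures: small synthetic datasets and the handcrafted
12-gene filtering table.

All fixtures are generated programmatically; nothing is read from disk
except through the package's own writers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from circapa.annotation import CountsTable
from circapa.simulate import SimConfig, simulate_dataset

TIME_GRID_2CYC_4H = np.arange(0.0, 48.0, 4.0)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=60, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def written_dataset(small_dataset, tmp_path_factory):
    from circapa.simulate import write_dataset

    annotation, truth, counts = small_dataset
    out = tmp_path_factory.mktemp("dataset")
    paths = write_dataset(annotation, truth, counts, out)
    return paths


def _gene_rows(gene_id, c_common, c_ext, totals):
    """Counts rows for one gene over the 12-point 2-cycle/4h grid.

    Scalars broadcast; sequences give per-time-point values.
    """
    n = len(TIME_GRID_2CYC_4H)
    cc = np.broadcast_to(np.asarray(c_common), (n,))
    ce = np.broadcast_to(np.asarray(c_ext), (n,))
    tot = np.broadcast_to(np.asarray(totals), (n,))
    return [
        (gene_id, float(t), int(cc[i]), int(ce[i]), int(tot[i]))
        for i, t in enumerate(TIME_GRID_2CYC_4H)
    ]


@pytest.fixture(scope="session")
def filter_fixture():
    """Twelve genes, each exercising exactly one filtering rule.

    All genes have L_c = L_e = 100 so psi_dist = c_ext / c_common
    exactly (unclamped).  Per-time-point totals are constant, and sum
    to 1,000,000 across genes so gJ's TPM is exactly 1.0.

    gA, gB, gK      clean survivors
    gC              19 3'UTR reads at t=0       -> coverage rule
    gD              exactly 20 reads everywhere -> kept (boundary)
    gE              psi_dist = 0.09 throughout  -> mean-psi rule
    gF              distal-dominant survivor (psi_dist = 0.8)
    gG              psi_dist = 0 at 2 of 12 pts -> zero rule (2 cycles)
    gH              psi_dist = 0 at 1 of 12 pts -> kept
    gI              gene totals 0, mean TPM 0   -> TPM rule
    gJ              mean TPM exactly 1.0        -> kept (boundary)
    gT              survivor whose three-isoform mean-psi profile
                    (0.5, 0.25, 0.25) tie-expands into two pairs
    """
    rows = []
    rows += _gene_rows("gA", 50, 30, 100_000)
    rows += _gene_rows("gB", 60, 24, 100_000)
    rows += _gene_rows("gC", [10] + [50] * 11, [9] + [30] * 11, 100_000)
    rows += _gene_rows("gD", 12, 8, 100_000)
    rows += _gene_rows("gE", 100, 9, 100_000)
    rows += _gene_rows("gF", 50, 40, 100_000)
    rows += _gene_rows("gG", [80, 80] + [50] * 10, [0, 0] + [30] * 10, 100_000)
    rows += _gene_rows("gH", [80] + [50] * 11, [0] + [30] * 11, 100_000)
    rows += _gene_rows("gI", 50, 30, 0)
    rows += _gene_rows("gJ", 50, 30, 1)
    rows += _gene_rows("gK", 55, 33, 100_000)
    rows += _gene_rows("gT", 50, 25, 99_999)
    counts = CountsTable(pd.DataFrame(rows, columns=CountsTable.COLUMNS))

    lengths = {g: 200 for g in counts.gene_ids}  # long-isoform UTR length
    seg_lengths = {g: (100, 100) for g in counts.gene_ids}

    expected = {
        "survivors": ["gA", "gB", "gD", "gF", "gH", "gJ", "gK", "gT"],
        "removed_coverage": ["gC"],
        "removed_mean_psi": ["gE"],
        "removed_zero_rule": ["gG"],
        "removed_tpm": ["gI"],
        # gT's isoform means at the selection stage
        "tie_gene_means": pd.DataFrame(
            {
                "gene_id": ["gT"] * 3,
                "isoform_id": ["iso1", "iso2", "iso3"],
                "mean_psi": [0.5, 0.25, 0.25],
            }
        ),
        "n_pairs": 9,  # 7 single pairs + 2 tie-expanded pairs for gT
    }
    return counts, lengths, seg_lengths, expected
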