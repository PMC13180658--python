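"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from scprs.io_harmonize import (CellPeakMatrix, GenotypeMatrix, PeakSet,
                                SumstatsTable)
from scprs.synthetic_data import SimConfig, simulate


def tiny_sim_config(**overrides) -> SimConfig:
    """A miniature simulation for fast unit tests."""
    base = dict(n_target=120, n_discovery=800, n_variants=400,
                n_chromosomes=2, haplotype_pool_size=60, n_cells=80,
                specific_peaks_per_type=15, shared_peaks=15,
                sigma=0.25, seed=7)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    return simulate(tiny_sim_config())


@pytest.fixture(scope="session")
def tiny_pipe(tiny_bundle):
    from scprs.workflows import prepare_features

    return prepare_features(tiny_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sumstats(chrom, pos, ref=None, alt=None, beta=None, pval=None,
                  maf=None, info=None, effect=None) -> SumstatsTable:
    n = len(pos)
    df = pd.DataFrame({
        "chrom": [str(c) for c in (chrom if not np.isscalar(chrom)
                                   else [chrom] * n)],
        "pos": list(pos),
        "ref": ref if ref is not None else ["A"] * n,
        "alt": alt if alt is not None else ["G"] * n,
        "beta": beta if beta is not None else [0.1] * n,
        "pval": pval if pval is not None else [0.01] * n,
        "maf": maf if maf is not None else [0.2] * n,
        "info": info if info is not None else [1.0] * n,
    })
    df["effect_allele"] = effect if effect is not None else df["alt"]
    return SumstatsTable(df=df)


def make_genotypes(dosages, chrom=None, pos=None, ref=None,
                   alt=None) -> GenotypeMatrix:
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return GenotypeMatrix(
        sample_ids=np.asarray([f"S{i}" for i in range(n)], dtype=object),
        variants=pd.DataFrame({
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else list(range(100, 100 + m)),
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
        }),
        dosages=d)


def make_cpm(counts, starts=None, width=100, chrom="1",
             cell_types=None) -> CellPeakMatrix:
    x = sparse.csr_matrix(np.asarray(counts))
    n_cells, n_peaks = x.shape
    if starts is None:
        starts = [i * width * 2 for i in range(n_peaks)]
    peaks = PeakSet(pd.DataFrame({
        "chrom": [chrom] * n_peaks,
        "start": starts,
        "end": [s + width for s in starts],
        "peak_id": [f"p{i}" for i in range(n_peaks)]}))
    return CellPeakMatrix(
        barcodes=np.asarray([f"C{i}" for i in range(n_cells)], dtype=object),
        peaks=peaks, matrix=x,
        cell_types=(np.asarray(cell_types, dtype=object)
                    if cell_types is not None else None))
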