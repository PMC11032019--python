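"""Normalization and roll-up stages for metabolome and proteome matrices.

The metabolome chain is: drop samples detecting fewer than 100 metabolites,
then mean-center each metabolite over its non-missing values.  The proteome
chain operates on log2 ion-current abundances: per-sample central-tendency
(median) normalization, then peptide-to-protein roll-up in the Rrollup
style — each peptide is scaled to the protein's reference peptide by the
median pairwise difference, and the protein profile is the per-sample
median of the scaled peptides.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_model import AbundanceMatrix, PeptideTable

logger = logging.getLogger(__name__)


def filter_sparse_samples(
    m: AbundanceMatrix, min_features: int = 100
) -> AbundanceMatrix:
    """Drop samples with fewer than ``min_features`` non-missing features.

    The threshold is strict ("fewer than"): a sample detecting exactly
    ``min_features`` features is retained.  Sample order is preserved.
    """
    counts = m.values.notna().sum(axis=1)
    keep = counts >= min_features
    removed = list(m.values.index[~keep])
    if removed:
        logger.info("filter_sparse_samples: removed %d samples: %s",
                    len(removed), removed)
    if not keep.any():
        raise ValueError("no samples survive filter")
    values = m.values.loc[keep]
    return AbundanceMatrix(values=values,
                           groups={s: m.groups[s] for s in values.index})


def center_metabolites(m: AbundanceMatrix) -> AbundanceMatrix:
    """Subtract each feature's mean over non-missing values.

    Features with no non-missing value at all are dropped (logged); missing
    cells stay missing.
    """
    all_missing = m.values.isna().all(axis=0)
    if all_missing.any():
        dropped = list(m.values.columns[all_missing])
        logger.info("center_metabolites: dropped all-missing features %s", dropped)
    values = m.values.loc[:, ~all_missing]
    centered = values - values.mean(axis=0, skipna=True)
    return AbundanceMatrix(values=centered, groups=dict(m.groups))


def log2_transform(m: AbundanceMatrix, pseudo: float = 0.0) -> AbundanceMatrix:
    """Elementwise log2(value + pseudo); non-positive arguments are an error."""
    shifted = m.values + pseudo
    bad = (shifted <= 0).stack()
    bad = bad[bad]
    if len(bad):
        sample, feature = bad.index[0]
        raise ValueError(
            f"non-positive abundance at sample {sample}, feature {feature} "
            f"(pseudo={pseudo})"
        )
    return AbundanceMatrix(values=np.log2(shifted), groups=dict(m.groups))


def central_tendency_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Align per-sample medians, preserving the global location.

    Each sample's median (over non-missing values) is subtracted and the
    grand median of the original per-sample medians is added back, so all
    samples end up with the same median and the overall scale is unmoved.
    Idempotent.  Values are expected to be on a log2 scale already.
    """
    if m.values.isna().all(axis=1).any():
        empty = m.values.index[m.values.isna().all(axis=1)][0]
        raise ValueError(f"sample {empty} has no values")
    medians = m.values.median(axis=1, skipna=True)
    grand = float(medians.median())
    values = m.values.sub(medians, axis=0) + grand
    return AbundanceMatrix(values=values, groups=dict(m.groups))


def _reference_peptide(block: pd.DataFrame) -> str:
    """Reference = most non-missing values; ties by higher median, then id."""
    counts = block.notna().sum(axis=1)
    medians = block.median(axis=1, skipna=True)
    order = sorted(
        block.index,
        key=lambda pep: (-int(counts[pep]), -float(medians[pep]), pep),
    )
    return order[0]


def rollup_proteins(p: PeptideTable, min_overlap: int = 3) -> AbundanceMatrix:
    """Roll peptide abundances up to protein profiles (Rrollup style).

    Per protein: the reference peptide is the one observed in the most
    samples (ties broken by higher median abundance, then lexicographic
    peptide id).  Every other peptide is shifted by the median of
    (reference - peptide) over samples where both are present, provided at
    least ``min_overlap`` shared samples (otherwise it is left unshifted).
    The protein abundance in a sample is the median of the shifted peptide
    values present there.  Input is expected on the log2, sample-normalized
    scale.
    """
    if len(p.values.index) == 0:
        raise ValueError("empty peptide table")

    by_protein: dict[str, list[str]] = {}
    for pep in p.values.index:
        by_protein.setdefault(p.protein_of[pep], []).append(pep)

    profiles = {}
    for protein in sorted(by_protein):
        block = p.values.loc[by_protein[protein]]
        ref = _reference_peptide(block)
        ref_row = block.loc[ref]
        shifted_rows = []
        for pep in block.index:
            row = block.loc[pep]
            if pep == ref:
                shifted_rows.append(row)
                continue
            diff = (ref_row - row).dropna()
            if len(diff) >= min_overlap:
                shifted_rows.append(row + float(diff.median()))
            else:
                shifted_rows.append(row)
        shifted = pd.DataFrame(shifted_rows)
        profiles[protein] = shifted.median(axis=0, skipna=True)

    values = pd.DataFrame(profiles)          # samples x proteins
    values = values.loc[p.samples]
    return AbundanceMatrix(values=values, groups=dict(p.groups))
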