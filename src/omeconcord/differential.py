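"""Differential-abundance calling per ome.

Transcriptome differential tables arrive precomputed from an external DE
pipeline and are only thresholded here (adjusted p < 0.05).  Metabolome
matrices are tested feature-by-feature with a two-tailed t test (Welch by
default) followed by Benjamini-Hochberg adjustment; the proteome uses
Welch's t test with a raw-p < 0.01 retention rule, as is conventional for
label-free protein abundance comparisons.  All thresholds are strict
inequalities.  No fold-change cutoff is applied at any stage.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import (
    AbundanceMatrix,
    DifferentialRecord,
    DifferentialTable,
    EnrichmentConfig,
)

logger = logging.getLogger(__name__)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, Satterthwaite df, two-sided p).

    The statistic is (mean(a) - mean(b)) / sqrt(s_a^2/n_a + s_b^2/n_b).
    Degenerate contrasts where both groups have zero variance yield
    (0, df, 1) when the means agree and an error when they differ.
    """
    a = np.asarray([x for x in a if not math.isnan(x)], dtype=float)
    b = np.asarray([x for x in b if not math.isnan(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate zero-variance contrast")
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(df), float(p)


def pooled_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Classic pooled-variance two-sample t test (the --pooled-t alternative)."""
    a = np.asarray([x for x in a if not math.isnan(x)], dtype=float)
    b = np.asarray([x for x in b if not math.isnan(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate zero-variance contrast")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(len(a) + len(b) - 2), float(p)


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = list(p)
    if not p:
        return []
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


def metabolite_sde(
    m: AbundanceMatrix,
    alpha: float = 0.05,
    pooled: bool = False,
    ome: str = "metabolome",
    tissue: str = "leaf",
) -> DifferentialTable:
    """Per-feature two-tailed t test (deficient vs replete) with BH adjustment.

    log2fc is mean(deficient) - mean(replete) on the working (normalized)
    scale.  Features testable in fewer than 2 samples per group are skipped
    with a log entry and excluded from the BH family.
    """
    test = pooled_t if pooled else welch_t
    def_samples = m.samples_in("deficient")
    rep_samples = m.samples_in("replete")
    if not def_samples or not rep_samples:
        raise ValueError("both conditions must be present")

    feats, lfcs, praws = [], [], []
    skipped = 0
    for feature in m.features:
        a = m.values.loc[def_samples, feature].dropna().to_numpy()
        b = m.values.loc[rep_samples, feature].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            skipped += 1
            continue
        try:
            _, _, p = test(a, b)
        except ValueError:
            # zero-variance contrast with distinct means: untestable by t
            skipped += 1
            continue
        feats.append(feature)
        lfcs.append(float(a.mean() - b.mean()))
        praws.append(p)
    if skipped:
        logger.info("metabolite_sde: skipped %d untestable features", skipped)

    padj = bh_adjust(praws)
    records = [
        DifferentialRecord(f, lfc, p, q, tissue=tissue, ome=ome)
        for f, lfc, p, q in zip(feats, lfcs, praws, padj)
    ]
    return DifferentialTable(records, tissue=tissue, ome=ome)


def call_sde(
    table: DifferentialTable, cfg: EnrichmentConfig | None = None
) -> tuple[set[str], dict[str, str]]:
    """Threshold a differential table into an SDE set and a direction map.

    Transcriptome and metabolome use adjusted p < de_alpha; the proteome
    uses raw p < proteome_alpha.  Direction is the sign of log2fc; features
    with log2fc exactly 0 are excluded from the direction map (warned).
    """
    cfg = cfg or EnrichmentConfig()
    sde: set[str] = set()
    directions: dict[str, str] = {}
    zero_fc = 0
    for r in table.records:
        if table.ome == "proteome":
            significant = r.p_raw < cfg.proteome_alpha
        else:
            if r.p_adj is None:
                raise ValueError(
                    f"{table.ome} table requires p_adj (feature {r.feature})"
                )
            significant = r.p_adj < cfg.de_alpha
        if not significant:
            continue
        sde.add(r.feature)
        if r.log2fc > 0:
            directions[r.feature] = "up"
        elif r.log2fc < 0:
            directions[r.feature] = "down"
        else:
            zero_fc += 1
    if zero_fc:
        logger.warning("call_sde: %d SDE features with log2fc == 0 carry no direction",
                       zero_fc)
    return sde, directions
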