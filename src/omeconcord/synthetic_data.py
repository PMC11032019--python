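"""Seeded generators for synthetic multi-omic inputs with planted effects.

The generators emulate the statistical structure the analysis assumes —
two tissues x two phosphate conditions with five replicates each, an
annotated feature universe with term sizes spanning roughly 5-500, planted
term-level enrichment with directional bias, metabolite matrices with
missing values and occasional sparse samples, and label-free peptide tables
with per-sample offsets and planted protein fold changes — so that every
pipeline stage can be exercised and its recovery measured offline.  Every
generator is a pure function of its parameters and seed and returns a
truth ledger recording exactly what was planted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import (
    AbundanceMatrix,
    DifferentialRecord,
    DifferentialTable,
    FeatureUniverse,
    PeptideTable,
    SyntheticTruth,
)

#: number of features left present in a deliberately sparse metabolome
#: sample — safely below the 100-feature detection filter
SPARSE_KEEP = 80


def generate_universe(
    n_features: int = 500,
    n_terms: int = 40,
    size_range: tuple[int, int] = (5, 50),
    seed: int = 0,
    namespace: str = "custom",
    kind: str = "gene",
) -> FeatureUniverse:
    """Annotated background with term sizes drawn log-uniformly.

    Term membership is sampled without replacement from the feature pool,
    so terms overlap only by chance, as flat GO/KEGG-style sets do.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi <= n_features):
        raise ValueError(f"infeasible term size range {size_range} "
                         f"for {n_features} features")
    rng = np.random.default_rng(seed)
    features = [f"g{i:04d}" for i in range(n_features)]
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi + 1), size=n_terms))
    sizes = np.clip(sizes.astype(int), lo, hi)
    terms = {}
    for j, size in enumerate(sizes):
        members = rng.choice(features, size=size, replace=False)
        tid = f"T{j:03d}"
        terms[tid] = (f"synthetic term {j}", frozenset(members.tolist()))
    return FeatureUniverse(features=frozenset(features), terms=terms,
                           namespace=namespace, kind=kind)


def plant_differential(
    universe: FeatureUniverse,
    tissues: tuple[str, ...] = ("leaf", "root"),
    sde_rate: float = 0.1,
    up_frac: float = 0.5,
    planted: list[tuple[str, tuple[str, ...], float, float]] | None = None,
    seed: int = 0,
    ome: str = "transcriptome",
) -> tuple[dict[str, DifferentialTable], SyntheticTruth]:
    """Summary-level differential tables with term-level planted effects.

    Background features are SDE with probability ``sde_rate`` per tissue
    and up-regulated with probability ``up_frac``.  Each planted tuple
    (term id, affected tissues, enrichment factor, up probability) makes
    the term's members SDE with probability min(1, sde_rate * factor) and
    up with the given probability, in the designated tissues.  Emitted
    tables carry p_adj 0.001 for SDE features and 0.5 otherwise, with
    log2fc +1 or -1 by direction — the post-DE contract the enrichment
    stage consumes.
    """
    if not (0.0 < sde_rate < 1.0) or not (0.0 < up_frac < 1.0):
        raise ValueError("rates must lie in (0,1)")
    planted = planted or []
    for term, _, factor, _ in planted:
        if term not in universe.terms:
            raise ValueError(f"planted term {term} absent from universe")
        if factor < 1.0:
            raise ValueError("enrichment factor must be >= 1")

    rng = np.random.default_rng(seed)
    features = sorted(universe.features)
    tables: dict[str, DifferentialTable] = {}
    planted_features: dict[str, list[str]] = {}

    for tissue in tissues:
        sde_prob = np.full(len(features), sde_rate)
        up_prob = np.full(len(features), up_frac)
        plant_mask = np.zeros(len(features), dtype=bool)
        index = {f: i for i, f in enumerate(features)}
        for term, affected, factor, term_up in planted:
            if tissue not in affected:
                continue
            for f in universe.term_members(term):
                i = index[f]
                sde_prob[i] = min(1.0, sde_rate * factor)
                up_prob[i] = term_up
                plant_mask[i] = True

        is_sde = rng.random(len(features)) < sde_prob
        is_up = rng.random(len(features)) < up_prob
        records = [
            DifferentialRecord(
                feature=f,
                log2fc=1.0 if is_up[i] else -1.0,
                p_raw=0.001 if is_sde[i] else 0.5,
                p_adj=0.001 if is_sde[i] else 0.5,
                tissue=tissue,
                ome=ome,
            )
            for i, f in enumerate(features)
        ]
        tables[tissue] = DifferentialTable(records, tissue=tissue, ome=ome)
        planted_features[tissue] = [
            f for i, f in enumerate(features) if plant_mask[i] and is_sde[i]
        ]

    truth = SyntheticTruth(
        seed=seed,
        planted_terms=[tuple(p) for p in planted],
        planted_features=planted_features,
        background={"sde_rate": sde_rate, "up_frac": up_frac},
    )
    return tables, truth


def generate_metabolome(
    n_per_group: int = 5,
    n_features: int = 200,
    effect_ids: tuple[str, ...] = (),
    shift: float = 3.0,
    missing_rate: float = 0.1,
    n_sparse_samples: int = 0,
    seed: int = 0,
) -> tuple[AbundanceMatrix, SyntheticTruth]:
    """Metabolite abundance matrix with planted group shifts and missingness.

    Baselines are Normal(mu_f, 1) with feature means mu_f ~ Normal(10, 1);
    effect features are shifted by ``shift`` in the deficient group (unit
    residual sd, so shift = 3 is a 3-sigma effect).  Cells go missing
    independently at ``missing_rate``; ``n_sparse_samples`` randomly chosen
    samples are additionally thinned to 80 present features to exercise the
    sub-100-feature detection filter.
    """
    if n_sparse_samples > 0 and n_features <= 100:
        raise ValueError("need > 100 features to construct sparse samples")
    rng = np.random.default_rng(seed)
    features = [f"m{i:04d}" for i in range(n_features)]
    samples = ([f"D{i+1}" for i in range(n_per_group)]
               + [f"R{i+1}" for i in range(n_per_group)])
    groups = {s: ("deficient" if s.startswith("D") else "replete")
              for s in samples}

    mu = rng.normal(10.0, 1.0, size=n_features)
    values = mu[None, :] + rng.normal(0.0, 1.0, size=(len(samples), n_features))
    effect_idx = [features.index(f) for f in effect_ids]
    values[: n_per_group, effect_idx] += shift

    mask = rng.random(values.shape) < missing_rate
    values[mask] = np.nan

    sparse = []
    if n_sparse_samples:
        sparse = sorted(rng.choice(samples, size=n_sparse_samples,
                                   replace=False).tolist())
        for s in sparse:
            i = samples.index(s)
            present = np.flatnonzero(~np.isnan(values[i]))
            keep = rng.choice(present, size=min(SPARSE_KEEP, len(present)),
                              replace=False)
            drop = np.setdiff1d(present, keep)
            values[i, drop] = np.nan

    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=samples, columns=features),
        groups=groups,
    )
    truth = SyntheticTruth(
        seed=seed,
        effects={"effect_ids": list(effect_ids), "shift": shift,
                 "sparse_samples": sparse},
        background={"missing_rate": missing_rate},
    )
    return matrix, truth


def generate_peptidome(
    n_proteins: int = 60,
    peptides_per_protein: tuple[int, int] = (2, 6),
    sample_offsets: tuple[float, ...] = (0.0,) * 10,
    fold_ids: tuple[str, ...] = (),
    log2_shift: float = 2.0,
    missing_rate: float = 0.05,
    noise_sd: float = 0.25,
    pep_offset_sd: float = 1.0,
    seed: int = 0,
) -> tuple[PeptideTable, SyntheticTruth]:
    """Label-free peptide table with per-sample offsets and planted folds.

    Protein base levels are Normal(20, 2) on the log2 scale; each peptide
    carries its own ionization offset Normal(0, 1); each sample adds the
    supplied loading offset; measurement noise is Normal(0, 0.25) (sd).
    ``fold_ids`` proteins are shifted by ``log2_shift`` in the deficient
    group (the first half of the samples).
    """
    n_samples = len(sample_offsets)
    if n_samples < 4 or n_samples % 2:
        raise ValueError("sample_offsets must cover an even number (>= 4) of samples")
    lo, hi = peptides_per_protein
    if not (1 <= lo <= hi):
        raise ValueError("invalid peptides-per-protein range")
    rng = np.random.default_rng(seed)

    half = n_samples // 2
    samples = ([f"D{i+1}" for i in range(half)]
               + [f"R{i+1}" for i in range(half)])
    groups = {s: ("deficient" if s.startswith("D") else "replete")
              for s in samples}
    offsets = np.asarray(sample_offsets, dtype=float)

    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    base = rng.normal(20.0, 2.0, size=n_proteins)
    fold_set = set(fold_ids)
    unknown = fold_set - set(proteins)
    if unknown:
        raise ValueError(f"fold proteins not generated: {sorted(unknown)}")

    rows = {}
    protein_of = {}
    for pidx, protein in enumerate(proteins):
        true = np.full(n_samples, base[pidx])
        if protein in fold_set:
            true[:half] += log2_shift
        n_pep = int(rng.integers(lo, hi + 1))
        for j in range(n_pep):
            pep = f"{protein}_pep{j}"
            pep_offset = rng.normal(0.0, pep_offset_sd) if pep_offset_sd else 0.0
            noise = (rng.normal(0.0, noise_sd, size=n_samples)
                     if noise_sd else np.zeros(n_samples))
            vals = true + pep_offset + offsets + noise
            miss = rng.random(n_samples) < missing_rate
            if miss.all():
                miss[rng.integers(n_samples)] = False
            vals = np.where(miss, np.nan, vals)
            rows[pep] = vals
            protein_of[pep] = protein

    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    table = PeptideTable(values=values, protein_of=protein_of, groups=groups)
    truth = SyntheticTruth(
        seed=seed,
        effects={
            "fold_ids": list(fold_ids),
            "log2_shift": log2_shift,
            "sample_offsets": list(offsets),
            "protein_base": dict(zip(proteins, base.tolist())),
        },
        background={"missing_rate": missing_rate},
    )
    return table, truth
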