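"""End-to-end orchestration: simulate / preprocess / test / enrich / crosstab.

A run is configured by a plain YAML mapping and is fully deterministic given
(inputs, config, seed); the run-metadata file written alongside the outputs
captures every threshold, interpretation flag and seed needed to reproduce
it.  Outputs carry no timestamps, so repeated runs are byte-identical.

Config layout (all paths relative to the config file's directory)::

    seed: 1
    config: {de_alpha: 0.05, ...}          # EnrichmentConfig overrides
    simulate:                              # either simulate ...
      universe: {n_features: 500, n_terms: 40, size_range: [5, 50]}
      differential:
        sde_rate: 0.1
        up_frac: 0.5
        planted: [[T000, [leaf, root], 10.0, 0.95]]
    annotations: {path: x.gmt, namespace: custom, kind: gene}   # ... or read
    tissues:
      leaf: {table: leaf.tsv, ome: transcriptome}
      root: {matrix: root.tsv, groups: groups.tsv, ome: metabolome}
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .crosstab import term_venn, venn_counts
from .differential import call_sde, metabolite_sde
from .enrichment import run_enrichment
from .io_model import (
    AbundanceMatrix,
    DifferentialTable,
    EnrichmentConfig,
    FeatureUniverse,
    read_abundance_matrix,
    read_annotation_map,
    read_differential_table,
    read_peptide_table,
    write_annotation_gmt,
    write_differential_table,
    write_enrichment_table,
)
from .preprocess import (
    center_metabolites,
    central_tendency_normalize,
    filter_sparse_samples,
    log2_transform,
    rollup_proteins,
)
from .synthetic_data import generate_universe, plant_differential

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def write_truth_tsv(truth, path: Path) -> None:
    """Flat (section, key, value) TSV rendering of a SyntheticTruth ledger."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("section\tkey\tvalue\n")
        fh.write(f"meta\tseed\t{truth.seed}\n")
        for term, tissues, factor, up in truth.planted_terms:
            fh.write(f"planted_term\t{term}\t{','.join(tissues)};"
                     f"factor={factor};up_prob={up}\n")
        for tissue, feats in truth.planted_features.items():
            fh.write(f"planted_features\t{tissue}\t{','.join(feats)}\n")
        for k, v in truth.background.items():
            fh.write(f"background\t{k}\t{v}\n")
        for k, v in truth.effects.items():
            fh.write(f"effects\t{k}\t{v}\n")


@_stage("simulate")
def _simulate(section: dict, seed: int, out: Path):
    uni_kw = dict(section.get("universe", {}))
    if "size_range" in uni_kw:
        uni_kw["size_range"] = tuple(uni_kw["size_range"])
    universe = generate_universe(seed=seed, **uni_kw)

    diff_kw = dict(section.get("differential", {}))
    planted = [
        (term, tuple(tissues), float(factor), float(up))
        for term, tissues, factor, up in diff_kw.pop("planted", [])
    ]
    tables, truth = plant_differential(
        universe, planted=planted, seed=seed + 1, **diff_kw
    )

    sim_dir = out / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    write_annotation_gmt(universe, sim_dir / "annotations.gmt")
    # unannotated features exist too: preserve the full background explicitly
    with open(sim_dir / "universe.txt", "w", encoding="utf-8") as fh:
        fh.writelines(f"{f}\n" for f in sorted(universe.features))
    for tissue, table in tables.items():
        write_differential_table(table, sim_dir / f"{tissue}.tsv")
    write_truth_tsv(truth, sim_dir / "truth.tsv")
    return universe, tables


@_stage("preprocess")
def _table_from_matrix(spec: dict, tissue: str, base: Path,
                       cfg: EnrichmentConfig) -> DifferentialTable:
    ome = spec.get("ome", "metabolome")
    if "peptides" in spec:
        pep = read_peptide_table(base / spec["peptides"], base / spec["groups"])
        if spec.get("log2", False):
            m = AbundanceMatrix(values=pep.values.T, groups=dict(pep.groups))
            m = log2_transform(m, pseudo=float(spec.get("pseudo", 0.0)))
            pep.values = m.values.T
        m = central_tendency_normalize(
            AbundanceMatrix(values=pep.values.T, groups=dict(pep.groups)))
        pep.values = m.values.T
        rolled = rollup_proteins(pep, min_overlap=int(spec.get("min_overlap", 3)))
        return metabolite_sde(rolled, alpha=cfg.de_alpha, ome="proteome",
                              tissue=tissue)
    matrix = read_abundance_matrix(base / spec["matrix"], base / spec["groups"])
    matrix = filter_sparse_samples(matrix,
                                   min_features=int(spec.get("min_features", 100)))
    matrix = center_metabolites(matrix)
    return metabolite_sde(matrix, alpha=cfg.de_alpha, ome=ome, tissue=tissue)


def run_pipeline(config: dict, out_dir: Path | str,
                 base_dir: Path | str = ".") -> Path:
    """Execute the full analysis described by ``config`` into ``out_dir``."""
    out = Path(out_dir)
    base = Path(base_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cfg = EnrichmentConfig(**config.get("config", {}))
    counts: dict[str, int | float] = {}

    # --- inputs: simulated or read from disk -------------------------------
    if "simulate" in config:
        universe, tables = _simulate(config["simulate"], seed, out)
    else:
        ann = config.get("annotations")
        if ann is None:
            raise StageError("enrich", ValueError("no annotation file configured"))
        try:
            universe = read_annotation_map(
                base / ann["path"],
                namespace=ann.get("namespace", "custom"),
                kind=ann.get("kind", "gene"),
                universe_path=(base / ann["universe"]) if ann.get("universe") else None,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc

        tables = {}
        for tissue, spec in config.get("tissues", {}).items():
            if "table" in spec:
                try:
                    tables[tissue] = read_differential_table(
                        base / spec["table"], tissue, spec.get("ome", "transcriptome"))
                except Exception as exc:  # noqa: BLE001
                    raise StageError("differential", exc) from exc
            else:
                tables[tissue] = _table_from_matrix(spec, tissue, base, cfg)

    diff_dir = out / "differential"
    diff_dir.mkdir(exist_ok=True)
    for tissue, table in sorted(tables.items()):
        write_differential_table(table, diff_dir / f"{tissue}.tsv")
        counts[f"features_{tissue}"] = len(table)

    # --- enrichment --------------------------------------------------------
    try:
        results = run_enrichment(tables, universe, cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc
    enrich_dir = out / "enrichment"
    enrich_dir.mkdir(exist_ok=True)
    categories = config.get("categories")  # optional term -> label passthrough
    write_enrichment_table(results, enrich_dir / "enrichment.tsv",
                           categories=categories)
    counts["terms_reported"] = len(results)
    counts["universe_size"] = universe.n_features

    # --- crosstab ----------------------------------------------------------
    cross_dir = out / "crosstab"
    cross_dir.mkdir(exist_ok=True)
    calls = {t: call_sde(tab, cfg) for t, tab in tables.items()}
    if set(calls) >= {"leaf", "root"}:
        sde_l, dir_l = calls["leaf"]
        sde_r, dir_r = calls["root"]
        feat = venn_counts(sde_l, dir_l, sde_r, dir_r)
        feat.to_frame().to_csv(cross_dir / "features.tsv", sep="\t",
                               index=False, float_format="%.6g")
        terms = term_venn(results, cfg)
        terms.to_frame().to_csv(cross_dir / "terms.tsv", sep="\t",
                                index=False, float_format="%.6g")
        counts["sde_leaf"] = len(sde_l)
        counts["sde_root"] = len(sde_r)
        counts["sde_shared"] = len(sde_l & sde_r)

    # --- run metadata ------------------------------------------------------
    meta = {
        "version": __version__,
        "seed": seed,
        "config": asdict(cfg),
        "counts": counts,
        "interpretation": {
            "p_both": cfg.p_both_method,
            "p_same": "product of concordant binomial tails",
            "central_tendency": "median",
            "pi": "fixed" if cfg.pi_fixed is not None else "estimated from SDE background",
        },
    }
    with open(out / "run_metadata.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return out
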