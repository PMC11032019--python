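"""Domain containers and TSV/GMT readers and writers.

Conventions shared by every table in the package:

* tab-separated, UTF-8; lines starting with ``#`` are ignored;
* an empty cell or the literal ``NA`` denotes a missing value — missing
  values are first-class (NaN in memory) and are never imputed as zero;
* feature identifiers are case-sensitive exact strings.  Transcript
  suffixes such as ``.1`` are *not* stripped unless a reader is explicitly
  asked to (silent id munging causes irreproducible overlaps).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("leaf", "root")
OMES = ("transcriptome", "proteome", "metabolome")
NAMESPACES = ("GO", "KEGG", "custom")
KINDS = ("gene", "protein", "metabolite")
CONDITIONS = ("deficient", "replete")

#: ordering used when sorting enrichment output rows
CONCORDANT_ORDER = {"both-up": 0, "both-down": 1, "any-direction": 2, "none": 3}

MISSING_TOKENS = {"", "NA"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureUniverse:
    """The annotated background against which enrichment is computed.

    ``features`` is the universe (defines N in the hypergeometric test);
    ``terms`` maps term id -> (term name, member feature set) and defines K.
    """

    features: frozenset[str]
    terms: dict[str, tuple[str, frozenset[str]]]
    namespace: str = "custom"
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        for term, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term} has no members")
            stray = members - self.features
            if stray:
                raise ValueError(
                    f"term {term} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def n_features(self) -> int:
        return len(self.features)

    def term_members(self, term: str) -> frozenset[str]:
        return self.terms[term][1]


@dataclass(frozen=True)
class DifferentialRecord:
    """One feature's differential-abundance result in one tissue and ome."""

    feature: str
    log2fc: float
    p_raw: float
    p_adj: float | None = None
    tissue: str = "leaf"
    ome: str = "transcriptome"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw out of [0,1] for {self.feature}: {self.p_raw}")
        if self.p_adj is not None and not (0.0 <= self.p_adj <= 1.0):
            raise ValueError(f"p_adj out of [0,1] for {self.feature}: {self.p_adj}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.ome not in OMES:
            raise ValueError(f"unknown ome {self.ome!r}")


@dataclass
class DifferentialTable:
    """Per-feature differential results for one tissue x ome, unique per feature."""

    records: list[DifferentialRecord]
    tissue: str
    ome: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.feature in seen:
                raise ValueError(f"duplicate feature {r.feature}")
            seen.add(r.feature)
            if r.tissue != self.tissue or r.ome != self.ome:
                raise ValueError(
                    f"record {r.feature} tissue/ome does not match table"
                )

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [r.feature for r in self.records],
                "log2fc": [r.log2fc for r in self.records],
                "p_raw": [r.p_raw for r in self.records],
                "p_adj": [np.nan if r.p_adj is None else r.p_adj for r in self.records],
            }
        )


@dataclass
class AbundanceMatrix:
    """Sample x feature abundance matrix with missing values and group labels.

    ``values`` is a DataFrame indexed by sample id with feature-id columns;
    NaN encodes missing.  Every sample must carry a condition label.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.values.index:
            if s not in self.groups:
                raise ValueError(f"ungrouped sample {s}")
        for s, g in self.groups.items():
            if g not in CONDITIONS:
                raise ValueError(f"unknown condition {g!r} for sample {s}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == condition]


@dataclass
class PeptideTable:
    """Peptide x sample abundances plus a peptide -> protein assignment."""

    values: pd.DataFrame            # peptides x samples
    protein_of: dict[str, str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        for pep in self.values.index:
            if pep not in self.protein_of:
                raise ValueError(f"peptide {pep} has no protein assignment")
        for s in self.values.columns:
            if s not in self.groups:
                raise ValueError(f"ungrouped sample {s}")
        empty = self.values.index[self.values.isna().all(axis=1)]
        if len(empty):
            raise ValueError(f"peptide {empty[0]} has no non-missing value")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def proteins(self) -> list[str]:
        return sorted(set(self.protein_of.values()))


@dataclass
class EnrichmentConfig:
    """Thresholds and interpretation flags for the enrichment stage.

    The defaults are the published cutoffs: adjusted-p 0.05 for
    transcriptome/metabolome SDE calls, raw-p 0.01 for the proteome,
    directionality cutoffs 0.95/0.05, and alpha 0.05 for the joint and
    same-direction statistics.
    """

    de_alpha: float = 0.05
    proteome_alpha: float = 0.01
    dir_hi: float = 0.95
    dir_lo: float = 0.05
    concord_alpha: float = 0.05
    min_term_size: int = 2
    pi_fixed: float | None = None       # None = estimate pi from the SDE background
    p_both_method: str = "intersection"  # or "fisher"

    def __post_init__(self) -> None:
        if not (0.0 < self.dir_lo < self.dir_hi < 1.0):
            raise ValueError("directionality cutoffs must satisfy 0 < lo < hi < 1")
        for name in ("de_alpha", "proteome_alpha", "concord_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1)")
        if self.p_both_method not in ("intersection", "fisher"):
            raise ValueError(f"unknown p_both method {self.p_both_method!r}")


@dataclass
class TissueStats:
    """Per-tissue enrichment block for one term."""

    k: int
    n: int
    K: int
    N: int
    p: float | None = None
    p_adj: float | None = None
    k_up: int = 0
    n_dir: int = 0
    pi: float | None = None
    p_pos: float | None = None
    call: str = "none"


@dataclass
class CrossStats:
    """Cross-tissue block: joint enrichment and direction concordance."""

    k_both: int
    n_both: int
    p_both: float | None = None
    p_both_adj: float | None = None
    p_same: float | None = None
    concordant_call: str = "none"


@dataclass
class EnrichmentResult:
    """Full statistic set for one term across tissues."""

    term: str
    name: str
    tissue_stats: dict[str, TissueStats]
    cross: CrossStats | None = None


@dataclass
class VennCells:
    count_leaf: int
    count_root: int
    count_shared: int
    count_leaf_unique: int
    count_root_unique: int
    shared_fraction: float

    def __post_init__(self) -> None:
        if self.count_leaf != self.count_leaf_unique + self.count_shared:
            raise ValueError("leaf count identity violated")
        if self.count_root != self.count_root_unique + self.count_shared:
            raise ValueError("root count identity violated")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared fraction outside [0,1]")


@dataclass
class CrosstabSummary:
    """Venn-style counts per direction class (all / up / down)."""

    classes: dict[str, VennCells]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in ("all", "up", "down"):
            c = self.classes[cls]
            rows.append(
                {
                    "class": cls,
                    "count_leaf": c.count_leaf,
                    "count_root": c.count_root,
                    "count_shared": c.count_shared,
                    "count_leaf_unique": c.count_leaf_unique,
                    "count_root_unique": c.count_root_unique,
                    "shared_fraction": c.shared_fraction,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SyntheticTruth:
    """Ledger of planted effects written by the synthetic generators."""

    seed: int
    planted_terms: list[tuple] = field(default_factory=list)
    planted_features: dict[str, list[str]] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=dict)
    effects: dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _data_lines(path: Path | str) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            yield i, line


def read_annotation_map(
    path: Path | str,
    namespace: str = "custom",
    kind: str = "gene",
    fmt: str = "auto",
    universe_path: Path | str | None = None,
) -> FeatureUniverse:
    """Read a term -> member annotation map (GMT or two-column TSV).

    GMT lines are ``term<TAB>name<TAB>member...``; two-column TSV rows are
    ``(term id, feature id)``.  ``fmt='auto'`` treats a file whose data
    lines all have exactly two fields as two-column TSV, otherwise GMT.
    Duplicate (term, feature) pairs collapse by set semantics.  By default
    the universe is the union of all members; an explicit one-id-per-line
    ``universe_path`` overrides it.
    """
    lines = list(_data_lines(path))
    if not lines:
        raise ValueError(f"no annotations in {path}")

    if fmt == "auto":
        fmt = "tsv" if all(len(l.split("\t")) == 2 for _, l in lines) else "gmt"
    if fmt not in ("gmt", "tsv"):
        raise ValueError(f"unknown annotation format {fmt!r}")

    terms: dict[str, tuple[str, set[str]]] = {}
    if fmt == "gmt":
        for lineno, line in lines:
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (no members)")
            term, name = parts[0], parts[1]
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: term {term} has no members")
            if term in terms:
                old_name, old = terms[term]
                terms[term] = (old_name, old | members)
            else:
                terms[term] = (name, members)
    else:
        for lineno, line in lines:
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed annotation row")
            term, feat = parts
            terms.setdefault(term, (term, set()))[1].add(feat)

    members_union: set[str] = set()
    for _, m in terms.values():
        members_union |= m

    if universe_path is not None:
        universe = {l for _, l in _data_lines(universe_path)}
        stray = members_union - universe
        if stray:
            raise ValueError(
                f"annotation members missing from explicit universe: {sorted(stray)[:5]}"
            )
    else:
        universe = members_union

    return FeatureUniverse(
        features=frozenset(universe),
        terms={t: (name, frozenset(m)) for t, (name, m) in sorted(terms.items())},
        namespace=namespace,
        kind=kind,
    )


def _parse_float(token: str) -> float | None:
    if token.strip() in MISSING_TOKENS:
        return None
    try:
        v = float(token)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def read_differential_table(
    path: Path | str, tissue: str, ome: str
) -> DifferentialTable:
    """Read a per-feature differential TSV (feature, log2fc, p_raw[, p_adj]).

    Rows whose p-values fail to parse are dropped with a logged count;
    duplicated feature ids are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"feature", "log2fc", "p_raw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_adj = "p_adj" in df.columns

    records: list[DifferentialRecord] = []
    seen: set[str] = set()
    dropped = 0
    for row in df.itertuples(index=False):
        feat = str(getattr(row, "feature"))
        p_raw = _parse_float(str(getattr(row, "p_raw")))
        lfc = _parse_float(str(getattr(row, "log2fc")))
        p_adj = _parse_float(str(getattr(row, "p_adj"))) if has_adj else None
        if p_raw is None or lfc is None or (has_adj and p_adj is None):
            dropped += 1
            continue
        if feat in seen:
            raise ValueError(f"duplicate feature {feat}")
        seen.add(feat)
        records.append(
            DifferentialRecord(feat, lfc, p_raw, p_adj, tissue=tissue, ome=ome)
        )
    if dropped:
        logger.info("read_differential_table(%s): dropped %d unparseable rows", path, dropped)
    return DifferentialTable(records, tissue=tissue, ome=ome)


def read_groups(path: Path | str) -> dict[str, str]:
    """Read a two-column sample -> condition map."""
    groups: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: malformed group row")
        if parts[0] == "sample" and parts[1] in ("group", "condition"):
            continue
        groups[parts[0]] = parts[1]
    if not groups:
        raise ValueError(f"no group assignments in {path}")
    return groups


def read_abundance_matrix(
    path: Path | str, groups_path: Path | str
) -> AbundanceMatrix:
    """Read a feature-per-row TSV matrix; columns beyond the first are samples."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    groups = read_groups(groups_path)
    for s in df.columns:
        if s not in groups:
            raise ValueError(f"ungrouped sample {s}")
    values = df.T.astype(float)          # -> samples x features
    return AbundanceMatrix(values=values, groups={s: groups[s] for s in values.index})


def read_peptide_table(path: Path | str, groups_path: Path | str) -> PeptideTable:
    """Read a peptide TSV (peptide, protein, samples...) plus a groups map."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], dtype={0: str})
    if "peptide" not in df.columns or "protein" not in df.columns:
        raise ValueError(f"{path}: need 'peptide' and 'protein' columns")
    if df["peptide"].duplicated().any():
        dup = df.loc[df["peptide"].duplicated(), "peptide"].iloc[0]
        raise ValueError(f"duplicate peptide {dup}")
    groups = read_groups(groups_path)
    sample_cols = [c for c in df.columns if c not in ("peptide", "protein")]
    for s in sample_cols:
        if s not in groups:
            raise ValueError(f"ungrouped sample {s}")
    values = df.set_index("peptide")[sample_cols].astype(float)
    protein_of = dict(zip(df["peptide"], df["protein"].astype(str)))
    return PeptideTable(
        values=values,
        protein_of=protein_of,
        groups={s: groups[s] for s in sample_cols},
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(v: float | None) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return format(v, ".6g")


def write_differential_table(table: DifferentialTable, path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\tlog2fc\tp_raw\tp_adj\n")
        for r in table.records:
            fh.write(
                f"{r.feature}\t{_fmt(r.log2fc)}\t{_fmt(r.p_raw)}\t{_fmt(r.p_adj)}\n"
            )


def write_abundance_matrix(m: AbundanceMatrix, path: Path | str) -> None:
    df = m.values.T  # features x samples on disk
    df.to_csv(path, sep="\t", na_rep="NA", index_label="feature",
              float_format="%.6g")


def write_groups(groups: Mapping[str, str], path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def write_peptide_table(p: PeptideTable, path: Path | str) -> None:
    df = p.values.copy()
    df.insert(0, "protein", [p.protein_of[pep] for pep in df.index])
    df.to_csv(path, sep="\t", na_rep="NA", index_label="peptide",
              float_format="%.6g")


ENRICHMENT_COLUMNS = [
    "term", "name", "K", "N",
    "k_leaf", "n_leaf", "p_leaf", "p_adj_leaf",
    "k_up_leaf", "n_dir_leaf", "pi_leaf", "p_pos_leaf", "call_leaf",
    "k_root", "n_root", "p_root", "p_adj_root",
    "k_up_root", "n_dir_root", "pi_root", "p_pos_root", "call_root",
    "k_both", "n_both", "p_both", "p_both_adj", "p_same", "concordant_call",
]


def write_enrichment_table(
    results: Sequence[EnrichmentResult],
    path: Path | str,
    categories: Mapping[str, str] | None = None,
) -> None:
    """Write one TSV row per term with the full statistic set.

    Rows are ordered by (concordant call class, p_both, term id) so output
    is deterministic; an optional user-supplied functional-category column
    is passed through unchanged.
    """

    def sort_key(r: EnrichmentResult):
        if r.cross is not None:
            call = r.cross.concordant_call
            p_both = r.cross.p_both if r.cross.p_both is not None else 1.0
        else:
            call, p_both = "none", 1.0
        return (CONCORDANT_ORDER.get(call, 9), p_both, r.term)

    header = list(ENRICHMENT_COLUMNS)
    if categories is not None:
        header.append("category")

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in sorted(results, key=sort_key):
            any_ts = next(iter(r.tissue_stats.values()))
            row: list[str] = [r.term, r.name, str(any_ts.K), str(any_ts.N)]
            for tissue in ("leaf", "root"):
                ts = r.tissue_stats.get(tissue)
                if ts is None:
                    row += ["NA"] * 9
                else:
                    row += [
                        str(ts.k), str(ts.n), _fmt(ts.p), _fmt(ts.p_adj),
                        str(ts.k_up), str(ts.n_dir), _fmt(ts.pi),
                        _fmt(ts.p_pos), ts.call,
                    ]
            if r.cross is None:
                row += ["NA", "NA", "NA", "NA", "NA", "NA"]
            else:
                c = r.cross
                row += [
                    str(c.k_both), str(c.n_both), _fmt(c.p_both),
                    _fmt(c.p_both_adj), _fmt(c.p_same), c.concordant_call,
                ]
            if categories is not None:
                row.append(categories.get(r.term, "NA"))
            fh.write("\t".join(row) + "\n")


def read_enrichment_table(path: Path | str) -> pd.DataFrame:
    """Round-trip reader for :func:`write_enrichment_table` output."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_annotation_gmt(universe: FeatureUniverse, path: Path | str) -> None:
    """Write the universe's terms in GMT format (term, name, members...)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term, (name, members) in sorted(universe.terms.items()):
            fh.write("\t".join([term, name, *sorted(members)]) + "\n")
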