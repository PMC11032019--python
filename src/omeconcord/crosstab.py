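"""Venn-style cross-tissue accounting of SDE features and significant terms.

Counts are produced per direction class (all, up, down).  For the up/down
classes a shared feature must carry that direction in *both* tissues; a
feature up in one tissue and down in the other counts toward the "all"
overlap only.  The shared fraction uses the union of the class across
tissues as its denominator (a per-tissue denominator is available).
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .io_model import (
    CrosstabSummary,
    EnrichmentConfig,
    EnrichmentResult,
    VennCells,
)


def _cells(leaf: set[str], root: set[str], denominator: str = "union") -> VennCells:
    shared = leaf & root
    union = leaf | root
    if denominator == "union":
        denom = len(union)
    elif denominator == "leaf":
        denom = len(leaf)
    elif denominator == "root":
        denom = len(root)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    frac = len(shared) / denom if denom else 0.0
    return VennCells(
        count_leaf=len(leaf),
        count_root=len(root),
        count_shared=len(shared),
        count_leaf_unique=len(leaf - shared),
        count_root_unique=len(root - shared),
        shared_fraction=frac,
    )


def venn_counts(
    sde_leaf: set[str],
    dir_leaf: Mapping[str, str],
    sde_root: set[str],
    dir_root: Mapping[str, str],
    denominator: str = "union",
) -> CrosstabSummary:
    """Cross-tissue overlap of SDE features, overall and by direction."""
    classes = {"all": _cells(set(sde_leaf), set(sde_root), denominator)}
    for direction in ("up", "down"):
        leaf_d = {f for f in sde_leaf if dir_leaf.get(f) == direction}
        root_d = {f for f in sde_root if dir_root.get(f) == direction}
        classes[direction] = _cells(leaf_d, root_d, denominator)
    return CrosstabSummary(classes=classes)


def term_venn(
    results: Sequence[EnrichmentResult],
    cfg: EnrichmentConfig | None = None,
    denominator: str = "union",
) -> CrosstabSummary:
    """Cross-tissue overlap of significant terms.

    Per-tissue sets hold terms with adjusted enrichment p < de_alpha (for
    up/down classes, additionally carrying that direction call).  The
    shared ("both") cell is populated only by terms whose joint-tissue
    statistic is significant (p_both_adj < concord_alpha; for up/down, a
    concordant both-up / both-down call) — not by naive set intersection.
    To keep the additive count identity, a both-cell term missing from a
    tissue's marginal set is still counted in that tissue's total.
    """
    cfg = cfg or EnrichmentConfig()

    def sig(ts) -> bool:
        return ts is not None and ts.p_adj is not None and ts.p_adj < cfg.de_alpha

    def build(direction: str | None, concordant: set[str]) -> VennCells:
        leaf, root = set(), set()
        for r in results:
            for tissue, bucket in (("leaf", leaf), ("root", root)):
                ts = r.tissue_stats.get(tissue)
                if sig(ts) and (direction is None or ts.call == direction):
                    bucket.add(r.term)
        shared = concordant
        leaf |= shared
        root |= shared
        union = leaf | root
        if denominator == "union":
            denom = len(union)
        elif denominator == "leaf":
            denom = len(leaf)
        else:
            denom = len(root)
        frac = len(shared) / denom if denom else 0.0
        return VennCells(
            count_leaf=len(leaf),
            count_root=len(root),
            count_shared=len(shared),
            count_leaf_unique=len(leaf - shared),
            count_root_unique=len(root - shared),
            shared_fraction=frac,
        )

    both_all = {
        r.term for r in results
        if r.cross is not None and r.cross.p_both_adj is not None
        and r.cross.p_both_adj < cfg.concord_alpha
    }
    both_up = {r.term for r in results
               if r.cross is not None and r.cross.concordant_call == "both-up"}
    both_down = {r.term for r in results
                 if r.cross is not None and r.cross.concordant_call == "both-down"}

    return CrosstabSummary(classes={
        "all": build(None, both_all),
        "up": build("up", both_up),
        "down": build("down", both_down),
    })
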