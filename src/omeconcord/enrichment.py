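"""Term-level enrichment and cross-tissue concordance statistics.

For each annotation term (a flat feature set) and tissue, over-representation
among that tissue's significantly differential (SDE) features is scored with
the hypergeometric upper tail against the annotated universe: with N the
universe size, K the term size, n the number of SDE features in the universe
and k the SDE term members, p = P(X >= k), X ~ Hypergeom(N, K, n).

Directional skew is scored with a binomial lower tail: with pi the
background up-fraction among a tissue's directed SDE features,
p_pos = P(X <= k_up), X ~ Binomial(n_dir, pi).  p_pos > 0.95 calls the term
up-regulated, p_pos < 0.05 down-regulated.

Two cross-tissue statistics combine the tissues: p_both is the
hypergeometric enrichment of the term within the *intersection* of the two
SDE sets (features differential in both tissues simultaneously), and p_same
is the product of the two tissues' concordant-direction binomial tail
probabilities, defined only when both tissues' direction calls agree (1
otherwise).  Both are thresholded at alpha = 0.05 after BH adjustment of
p_both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .differential import bh_adjust, call_sde
from .io_model import (
    CrossStats,
    DifferentialTable,
    EnrichmentConfig,
    EnrichmentResult,
    FeatureUniverse,
    TissueStats,
)

logger = logging.getLogger(__name__)


@dataclass
class TissueSdeContext:
    """One tissue's SDE set restricted to the universe, with directions."""

    tissue: str
    sde: frozenset[str]
    directions: dict[str, str]       # feature -> up/down; zero-fc features absent
    pi: float                        # background up-fraction among directed SDE

    @classmethod
    def from_sets(
        cls,
        tissue: str,
        sde: set[str],
        directions: dict[str, str],
        universe: FeatureUniverse,
        pi_fixed: float | None = None,
    ) -> "TissueSdeContext":
        sde_u = frozenset(sde & universe.features)
        dirs = {f: d for f, d in directions.items() if f in sde_u}
        if pi_fixed is not None:
            pi = pi_fixed
        else:
            n_dir = len(dirs)
            pi = (sum(1 for d in dirs.values() if d == "up") / n_dir
                  if n_dir else 0.5)
        return cls(tissue=tissue, sde=sde_u, directions=dirs, pi=pi)

    @classmethod
    def from_table(
        cls,
        table: DifferentialTable,
        universe: FeatureUniverse,
        cfg: EnrichmentConfig,
    ) -> "TissueSdeContext":
        sde, directions = call_sde(table, cfg)
        return cls.from_sets(table.tissue, sde, directions, universe,
                             pi_fixed=cfg.pi_fixed)


# ---------------------------------------------------------------------------
# elementary tails
# ---------------------------------------------------------------------------

def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"invalid hypergeometric parameters K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binom_lower(k: int, n: int, pi: float) -> float:
    """P(X <= k), X ~ Binomial(n, pi)."""
    return float(stats.binom.cdf(k, n, pi))


def binom_upper(k: int, n: int, pi: float) -> float:
    """P(X >= k), X ~ Binomial(n, pi)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, pi))


def directionality(
    k_up: int, n_term: int, pi: float, cfg: EnrichmentConfig | None = None
) -> tuple[float, str]:
    """Binomial lower-tail directionality score and call for one term.

    p_pos = P(X <= k_up) under Binomial(n_term, pi); the printed cutoffs act
    directly on it: > dir_hi is an up call, < dir_lo a down call.
    """
    cfg = cfg or EnrichmentConfig()
    if n_term < 1:
        raise ValueError("n_term must be >= 1")
    if not (0 <= k_up <= n_term):
        raise ValueError(f"k_up={k_up} outside [0, n_term={n_term}]")
    if not (0.0 <= pi <= 1.0):
        raise ValueError("pi must lie in [0,1]")
    p_pos = binom_lower(k_up, n_term, pi)
    if p_pos > cfg.dir_hi:
        call = "up"
    elif p_pos < cfg.dir_lo:
        call = "down"
    else:
        call = "none"
    return p_pos, call


# ---------------------------------------------------------------------------
# per-tissue and cross-tissue term statistics
# ---------------------------------------------------------------------------

def enrich_tissue(
    ctx: TissueSdeContext,
    universe: FeatureUniverse,
    cfg: EnrichmentConfig | None = None,
) -> dict[str, TissueStats]:
    """Hypergeometric enrichment plus directionality for every reportable term.

    Terms with fewer than ``cfg.min_term_size`` SDE members are skipped.
    BH adjustment runs across all tested terms of this tissue x namespace.
    """
    cfg = cfg or EnrichmentConfig()
    if not ctx.sde:
        raise ValueError("no SDE features")
    N = universe.n_features
    n = len(ctx.sde)

    stats_by_term: dict[str, TissueStats] = {}
    tested: list[str] = []
    pvals: list[float] = []
    for term, (_, members) in universe.terms.items():
        hits = members & ctx.sde
        k = len(hits)
        if k < cfg.min_term_size:
            continue
        p = hypergeom_upper(k, len(members), n, N)
        directed = [f for f in hits if f in ctx.directions]
        k_up = sum(1 for f in directed if ctx.directions[f] == "up")
        n_dir = len(directed)
        if n_dir >= 1:
            p_pos, call = directionality(k_up, n_dir, ctx.pi, cfg)
        else:
            p_pos, call = None, "none"
        stats_by_term[term] = TissueStats(
            k=k, n=n, K=len(members), N=N, p=p, k_up=k_up, n_dir=n_dir,
            pi=ctx.pi, p_pos=p_pos, call=call,
        )
        tested.append(term)
        pvals.append(p)

    for term, q in zip(tested, bh_adjust(pvals)):
        stats_by_term[term].p_adj = q
    return stats_by_term


def joint_enrichment(
    ctx_root: TissueSdeContext,
    ctx_leaf: TissueSdeContext,
    universe: FeatureUniverse,
    cfg: EnrichmentConfig | None = None,
) -> dict[str, tuple[int, int, float]]:
    """Per-term joint-tissue enrichment: term -> (k_both, n_both, p_both).

    The default construction scores the term within the intersection of the
    two tissues' SDE sets against the same universe; the Fisher alternative
    combines the two marginal hypergeometric p-values instead.  BH over the
    returned family is applied by the caller (one family per namespace).
    """
    cfg = cfg or EnrichmentConfig()
    both = ctx_root.sde & ctx_leaf.sde
    n_both = len(both)
    if n_both == 0:
        logger.warning("joint_enrichment: empty SDE intersection; all p_both = 1")
    N = universe.n_features

    out: dict[str, tuple[int, int, float]] = {}
    for term, (_, members) in universe.terms.items():
        k_both = len(members & both)
        if cfg.p_both_method == "fisher":
            p_r = hypergeom_upper(len(members & ctx_root.sde), len(members),
                                  len(ctx_root.sde), N)
            p_l = hypergeom_upper(len(members & ctx_leaf.sde), len(members),
                                  len(ctx_leaf.sde), N)
            p_both = float(stats.combine_pvalues([p_r, p_l], method="fisher")[1])
        elif n_both == 0:
            p_both = 1.0
        else:
            p_both = hypergeom_upper(k_both, len(members), n_both, N)
        out[term] = (k_both, n_both, p_both)
    return out


def same_direction(
    root: tuple[int, int, float],
    leaf: tuple[int, int, float],
    cfg: EnrichmentConfig | None = None,
) -> tuple[float, str]:
    """Concordant-direction probability across tissues for one term.

    Each tissue block is (k_up, n_dir, pi).  With u_t = P(X_t >= k_up) and
    d_t = P(X_t <= k_up) under independent Binomial(n_t, pi_t) nulls:
    if both tissues call up, p_same = u_root * u_leaf ("both-up"); if both
    call down, p_same = d_root * d_leaf ("both-down"); otherwise p_same = 1.
    """
    cfg = cfg or EnrichmentConfig()
    calls = []
    for k_up, n_dir, pi in (root, leaf):
        if n_dir < 1:
            return 1.0, "none"
        _, call = directionality(k_up, n_dir, pi, cfg)
        calls.append(call)
    if calls[0] == calls[1] == "up":
        p = (binom_upper(root[0], root[1], root[2])
             * binom_upper(leaf[0], leaf[1], leaf[2]))
        return p, "both-up"
    if calls[0] == calls[1] == "down":
        p = (binom_lower(root[0], root[1], root[2])
             * binom_lower(leaf[0], leaf[1], leaf[2]))
        return p, "both-down"
    return 1.0, "none"


def run_enrichment(
    tables: dict[str, DifferentialTable],
    universe: FeatureUniverse,
    cfg: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Assemble the full per-term statistic set across one or two tissues.

    For two-tissue input the cross block carries joint enrichment (p_both,
    BH-adjusted per namespace) and the same-direction statistic; the final
    concordant call is "both-up"/"both-down" when the joint enrichment is
    significant and both direction calls agree with p_same < alpha,
    "any-direction" when only the joint enrichment is significant, "none"
    otherwise.
    """
    cfg = cfg or EnrichmentConfig()
    if not tables:
        raise ValueError("at least one tissue table required")
    contexts = {
        tissue: TissueSdeContext.from_table(t, universe, cfg)
        for tissue, t in tables.items()
    }
    per_tissue = {
        tissue: enrich_tissue(ctx, universe, cfg)
        for tissue, ctx in contexts.items()
    }

    reported = sorted(set().union(*(d.keys() for d in per_tissue.values())))

    cross_raw: dict[str, tuple[int, int, float]] = {}
    if set(contexts) >= {"root", "leaf"}:
        joint = joint_enrichment(contexts["root"], contexts["leaf"],
                                 universe, cfg)
        cross_raw = {t: joint[t] for t in reported}
        adj = bh_adjust([cross_raw[t][2] for t in reported])
        p_both_adj = dict(zip(reported, adj))

    results: list[EnrichmentResult] = []
    N = universe.n_features
    for term in reported:
        name, members = universe.terms[term]
        tissue_stats: dict[str, TissueStats] = {}
        for tissue, ctx in contexts.items():
            ts = per_tissue[tissue].get(term)
            if ts is None:
                hits = members & ctx.sde
                ts = TissueStats(k=len(hits), n=len(ctx.sde), K=len(members),
                                 N=N, pi=ctx.pi)
            tissue_stats[tissue] = ts

        cross = None
        if cross_raw:
            k_both, n_both, p_both = cross_raw[term]
            q = p_both_adj[term]
            blocks = {}
            for tissue in ("root", "leaf"):
                ts = tissue_stats[tissue]
                blocks[tissue] = (ts.k_up, ts.n_dir, contexts[tissue].pi)
            p_same, concord = same_direction(blocks["root"], blocks["leaf"], cfg)
            if q < cfg.concord_alpha:
                if concord in ("both-up", "both-down") and p_same < cfg.concord_alpha:
                    final = concord
                else:
                    final = "any-direction"
            else:
                final = "none"
            cross = CrossStats(k_both=k_both, n_both=n_both, p_both=p_both,
                               p_both_adj=q, p_same=p_same,
                               concordant_call=final)
        results.append(EnrichmentResult(term=term, name=name,
                                        tissue_stats=tissue_stats, cross=cross))
    return results
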