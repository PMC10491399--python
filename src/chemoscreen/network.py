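"""Hit-list significance on protein-interaction networks and gene sets.

Two procedures assess whether a screen's hit list is biologically
coherent:

* **Degree-preserving shuffle test.** After removing hub hits (>= 200
  interaction partners, which would trivially inflate connectivity), the
  observed statistic is the number of unique interactions between hit
  proteins. The null redirects every interaction stub of every hit to a
  random protein drawn with probability proportional to its degree (a
  configuration-model-style null that preserves the degree sequence in
  expectation) and counts how often the replacement is itself a hit. The
  empirical p uses the add-one rule, so 0 exceedances in 10,000 shuffles
  reports p < 1e-4, never 0. The null statistic has the closed-form
  expectation D_H^2 / D_total (D_H = summed hit degrees), used as a
  cross-check. Because a hit-hit edge contributes a stub from both
  endpoints while the observed count is unique edges, the null statistic
  is asymmetric relative to the observed count; a documented symmetric
  variant (each hit-incident edge redirected once) is available via
  ``variant="edge"`` for sensitivity analysis.

* **Gene-set over-representation.** One-sided Fisher's exact
  (hypergeometric upper-tail) test per term against a stated gene
  universe, BH-corrected across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .integrate import bh_fdr
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_MAX_PARTNERS = 200
DEFAULT_N_SHUFFLES = 10_000


def filter_hubs(
    net: nx.Graph, hits: set[str], max_partners: int = DEFAULT_MAX_PARTNERS
) -> tuple[nx.Graph, set[str], list[str]]:
    """Remove hit proteins with at least ``max_partners`` interaction partners.

    Removed hubs leave both the hit set and the graph, so they contribute
    neither to the observed edge count nor to the null. Returns the
    filtered graph, filtered hit set and the sorted list of removed hubs.
    """
    if max_partners < 1:
        raise ConfigurationError("max_partners must be >= 1")
    removed = sorted(
        h for h in hits if h in net and net.degree[h] >= max_partners
    )
    if not removed:
        return net, set(hits), []
    logger.info("removing %d hub hit(s): %s", len(removed), ", ".join(removed))
    out = net.copy()
    out.remove_nodes_from(removed)
    return out, set(hits) - set(removed), removed


def count_hit_edges(net: nx.Graph, hits: set[str]) -> int:
    """Number of unique interactions between different hit proteins."""
    absent = {h for h in hits if h not in net}
    if absent:
        logger.warning("%d hit(s) absent from the network dropped: %s",
                       len(absent), ", ".join(sorted(absent)))
    present = set(hits) - absent
    return sum(1 for a, b in net.edges(present) if a in present and b in present)


@dataclass(frozen=True)
class ShuffleTestResult:
    observed_edges: int
    null_counts: np.ndarray
    expected_null: float
    empirical_p: float
    n_shuffles: int
    removed_hubs: list[str]
    seed: int
    variant: str = "stub"

    def to_dict(self) -> dict:
        return {
            "observed_edges": self.observed_edges,
            "expected_null": self.expected_null,
            "null_mean": float(self.null_counts.mean()),
            "empirical_p": self.empirical_p,
            "n_shuffles": self.n_shuffles,
            "removed_hubs": self.removed_hubs,
            "seed": self.seed,
            "variant": self.variant,
        }


def shuffle_test(
    net: nx.Graph,
    hits: set[str],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    max_partners: int | None = DEFAULT_MAX_PARTNERS,
    variant: str = "stub",
) -> ShuffleTestResult:
    """Degree-preserving shuffling significance of hit interconnectivity.

    Per shuffle, every interaction partner slot of every hit is refilled by
    a protein drawn with probability proportional to its degree, and the
    statistic counts how many replacements are themselves hits. Stubs are
    redirected independently; no simple-graph constraint is imposed on the
    shuffled configuration. ``max_partners=None`` skips hub filtering
    (useful when inputs were filtered already).
    """
    if n_shuffles < 100:
        raise ConfigurationError("n_shuffles must be >= 100")
    if variant not in ("stub", "edge"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    removed: list[str] = []
    if max_partners is not None:
        net, hits, removed = filter_hubs(net, hits, max_partners)
    if net.number_of_edges() == 0:
        raise ValidationError("network has no edges")
    hits = {h for h in hits if h in net}
    if not hits:
        raise ValidationError("no hit proteins present in the network")

    observed = count_hit_edges(net, hits)
    nodes = list(net.nodes)
    degrees = np.array([net.degree[v] for v in nodes], dtype=float)
    total_degree = degrees.sum()
    is_hit = np.array([v in hits for v in nodes])
    hit_degree = degrees[is_hit].sum()
    expected_null = hit_degree * hit_degree / total_degree

    n_stubs = int(hit_degree)
    if variant == "edge":
        # redirect each hit-incident edge once instead of once per endpoint
        n_stubs -= observed
        expected_null = n_stubs * hit_degree / total_degree
    rng = np.random.default_rng(seed)
    cumw = np.cumsum(degrees / total_degree)
    cumw[-1] = 1.0
    draws = np.searchsorted(cumw, rng.random(n_shuffles * n_stubs), side="right")
    null = is_hit[draws].reshape(n_shuffles, n_stubs).sum(axis=1)
    p = (1.0 + int(np.count_nonzero(null >= observed))) / (1.0 + n_shuffles)
    return ShuffleTestResult(
        observed_edges=observed, null_counts=null,
        expected_null=float(expected_null), empirical_p=p,
        n_shuffles=n_shuffles, removed_hubs=removed, seed=seed, variant=variant,
    )


# ---------------------------------------------------------------------------
# gene-set over-representation
# ---------------------------------------------------------------------------

def gene_set_enrichment(
    hits: set[str], universe: set[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, BH-corrected.

    Hits outside the universe are dropped with a warning; term member sets
    are intersected with the universe; terms with no universe overlap are
    skipped. Returns a DataFrame sorted by p-value.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    stray = hits - universe
    if stray:
        logger.warning("%d hit(s) outside the universe dropped", len(stray))
    hits = hits & universe
    n_universe, n_hits = len(universe), len(hits)
    rows = []
    for term in sets.values():
        members = term.members & universe
        if not members:
            continue
        overlap = len(members & hits)
        term_size = len(members)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, term_size, n_hits))
        a = overlap
        b = n_hits - overlap
        c = term_size - overlap
        d = n_universe - n_hits - c
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((term.term_id, term.term_name, overlap, term_size,
                     n_hits, n_universe, odds, p))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "overlap",
                                      "term_size", "hit_size", "universe_size",
                                      "odds_ratio", "p_value"])
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = []
    return out
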