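"""Category/complex enrichment, per-screen coverage matrix, kinase summaries.

Over-representation is tested with the one-sided hypergeometric upper tail
(the Fisher exact test's one-sided p-value) and adjusted across categories
with Benjamini-Hochberg.  The universe — by default every protein quantified
in at least one screen — materially changes p-values and is recorded in every
result frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .screen_io import CategorySet

logger = logging.getLogger(__name__)

DEFAULT_MIN_CATEGORY = 3
DEFAULT_MAX_CATEGORY = 2000


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """One-sided upper-tail p-value ``P(X >= k)``, X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` category size, ``n`` draws (hits), ``k``
    observed overlap.  Computed via the survival function in log space, so
    tiny tails are stable.  ``k = 0`` returns exactly 1 (the whole support).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    logp = sps.hypergeom.logsf(k - 1, N, K, n)
    p = float(min(1.0, np.exp(logp)))
    # tails beyond ~1e-308 underflow exp(); clamp to the smallest positive
    # double so the result stays in (0, 1]
    return p if p > 0.0 else 5e-324


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, aligned to input order.

    All inputs must lie in (0, 1]; adjusted values are monotone in the sorted
    order and never smaller than the raw p.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_categories(
    hit_set: set[str],
    categories: CategorySet,
    *,
    min_size: int = DEFAULT_MIN_CATEGORY,
    max_size: int = DEFAULT_MAX_CATEGORY,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hit_set`` in every category.

    Categories outside ``[min_size, max_size]`` (size within the universe)
    are not tested; BH adjustment runs across exactly the tested categories.
    Returns a frame sorted by ``p_adj`` then ``p`` with columns
    ``category_id``, ``name``, ``k``, ``K``, ``n``, ``N``, ``p``, ``p_adj``.
    """
    universe = categories.universe
    hits = set(hit_set) & universe
    if not hits:
        raise ValueError("empty hit set (after universe restriction)")
    if len(hit_set) != len(hits):
        logger.warning("%d hits outside the universe ignored", len(hit_set) - len(hits))
    N, n = len(universe), len(hits)
    rows = []
    for cid, (name, members) in sorted(categories.categories.items()):
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        k = len(members & hits)
        rows.append({"category_id": cid, "name": name, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_tail(k, K, n, N)})
    df = pd.DataFrame(rows, columns=["category_id", "name", "k", "K", "n", "N", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"])
        df = df.sort_values(["p_adj", "p", "category_id"], kind="stable").reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df


def category_screen_matrix(
    categories: CategorySet,
    screen_hits: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Category x screen matrix of member-hit counts.

    Each cell counts the category members that are hits in that screen; the
    ``any_screen`` column counts distinct members hitting at least one screen
    (the "66 out of 125" style coverage number), and ``size`` the category
    size in the universe.
    """
    sids = list(screen_hits)
    rows = []
    for cid, (name, members) in sorted(categories.categories.items()):
        row = {"category_id": cid, "name": name, "size": len(members)}
        any_hit: set[str] = set()
        for sid in sids:
            overlap = members & screen_hits[sid]
            row[sid] = len(overlap)
            any_hit |= overlap
        row["any_screen"] = len(any_hit)
        rows.append(row)
    return pd.DataFrame(rows, columns=["category_id", "name", "size", *sids, "any_screen"])


@dataclass
class KinaseNeighborhood:
    """UV-phosphorylation summary of one kinase's interaction neighborhood."""

    kinase_id: str
    interactors: set[str]
    n_phospho_up: int
    fraction: float  # 0.0 with undefined=True when there are no interactors
    undefined: bool = False
    cross_flags: pd.DataFrame = field(default_factory=pd.DataFrame)


def kinase_phospho_summary(
    network: nx.Graph,
    kinases: Iterable[str],
    phospho_up: set[str],
    cross_flags: Mapping[str, set[str]] | None = None,
) -> list[KinaseNeighborhood]:
    """Count UV-phosphorylated interactors per queried kinase.

    ``phospho_up`` is the set of proteins with at least one UV-increased
    phosphosite.  ``cross_flags`` maps flag names (e.g. ``rnai_low``,
    ``csb_interactor``) to protein sets; each interactor is annotated with
    every flag for the Fig-5-style annex.  A kinase absent from the network
    yields an empty neighborhood with a warning.
    """
    cross_flags = dict(cross_flags or {})
    out = []
    for kin in kinases:
        if kin in network:
            inter = set(network[kin])
        else:
            logger.warning("kinase %s absent from the interaction network", kin)
            inter = set()
        n_up = len(inter & phospho_up)
        undefined = len(inter) == 0
        frac = 0.0 if undefined else n_up / len(inter)
        flags = pd.DataFrame(
            {
                "protein_id": sorted(inter),
                "phospho_up": [p in phospho_up for p in sorted(inter)],
                **{
                    name: [p in members for p in sorted(inter)]
                    for name, members in cross_flags.items()
                },
            }
        )
        out.append(
            KinaseNeighborhood(
                kinase_id=kin,
                interactors=inter,
                n_phospho_up=n_up,
                fraction=frac,
                undefined=undefined,
                cross_flags=flags,
            )
        )
    return out
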