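"""Gene prioritization across screens: count, aggregate and weighted scores.

Three ranked score lists are produced over the union universe of all
quantified proteins:

* **count score** — one point per screen in which the gene passes the Z
  threshold (0-6 with the six-screen design; the full-data analogue topped
  out at two genes, RPA1 and ASCC3, scoring in all six).
* **aggregate score** — the unweighted sum of per-screen normalized scores.
  Each screen's Z-scores are first converted to fractional ranks in the
  response direction (best = 1.0, worst = 1/n; unquantified genes score 0),
  because raw Z scales differ wildly between MS screens and the RNAi screen.
* **weighted score** — the same normalized scores combined with per-screen
  weights derived from a gold-standard *training category* of known
  transcription-repair coupling factors: a screen's information value is the
  -log10 one-sided hypergeometric enrichment of the gold set among its hits,
  and the weights are those values normalized to sum 1.  The weighted score
  lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import hypergeom_tail

logger = logging.getLogger(__name__)

MAX_RAW_WEIGHT = 300.0  # cap on -log10(p); ~smallest positive double


@dataclass
class ScreenWeights:
    """Per-screen weights (sum 1) plus the raw -log10 enrichment they came from."""

    weights: dict[str, float]
    raw: dict[str, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()))
        if (w < 0).any():
            raise ValueError("negative weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum()}, not 1")

    @classmethod
    def uniform(cls, screen_ids: Iterable[str]) -> "ScreenWeights":
        ids = list(screen_ids)
        return cls(weights={s: 1.0 / len(ids) for s in ids}, raw={s: 0.0 for s in ids})


def normalize_screen_score(z: pd.Series, tail: str = "+") -> pd.Series:
    """Fractional-rank normalization of one screen's Z-scores.

    The gene with the strongest response-direction Z gets 1.0, the weakest
    1/n; ties share the mean of their fractional ranks.  ``tail`` orients the
    response: "+" ranks by z, "-" by -z, "both" by |z|.
    """
    zs = pd.Series(z, dtype=float)
    if tail == "+":
        resp = zs.to_numpy()
    elif tail == "-":
        resp = -zs.to_numpy()
    elif tail == "both":
        resp = np.abs(zs.to_numpy())
    else:
        raise ValueError(f"bad tail {tail!r}")
    ranks = sps.rankdata(resp, method="average")
    return pd.Series(ranks / len(ranks), index=zs.index)


def count_score(hit_flags: Mapping[str, bool]) -> int:
    """Number of screens in which the gene is a hit."""
    return int(sum(bool(v) for v in hit_flags.values()))


def aggregate_z_score(normalized_scores: Mapping[str, float]) -> float:
    """Unweighted sum of per-screen normalized scores (0 to #screens)."""
    return float(sum(normalized_scores.values()))


def weighted_score(normalized_scores: Mapping[str, float], weights: ScreenWeights) -> float:
    """Convex combination of normalized scores under the screen weights."""
    return float(sum(weights.weights[s] * v for s, v in normalized_scores.items()))


def screen_information_weights(
    hit_sets: Mapping[str, set[str]],
    universes: Mapping[str, set[str]],
    gold: set[str],
) -> ScreenWeights:
    """Benchmark each screen against the training category and derive weights.

    For screen *i* with quantified universe ``N_i``, hit set ``n_i`` and gold
    overlap ``k_i`` (gold restricted to the screen's universe, ``K_i``), the
    raw information value is ``-log10`` of the one-sided hypergeometric
    upper-tail p-value, capped at 300.  Weights are raw values normalized to
    sum 1; if every screen has zero information the weights fall back to
    uniform with a warning.
    """
    raw: dict[str, float] = {}
    for sid in hit_sets:
        uni = universes[sid]
        hits = hit_sets[sid] & uni
        if not hits:
            raise ValueError(f"screen {sid} has no hits")
        gold_in = gold & uni
        k = len(hits & gold_in)
        p = hypergeom_tail(k, len(gold_in), len(hits), len(uni)) if gold_in else 1.0
        raw[sid] = min(MAX_RAW_WEIGHT, max(0.0, -np.log10(p)))
    total = sum(raw.values())
    if total == 0.0:
        logger.warning("no screen shows gold enrichment; using uniform weights")
        return ScreenWeights.uniform(list(raw))
    return ScreenWeights(weights={s: v / total for s, v in raw.items()}, raw=raw)


def benchmark_median(scores: Mapping[str, float], gold: Iterable[str]) -> float:
    """Median score of the training-category members under one scheme.

    Members missing from the score table enter as 0 (counted and warned).
    """
    gold = list(gold)
    if not gold:
        raise ValueError("empty gold set")
    missing = [g for g in gold if g not in scores]
    if missing:
        logger.warning("%d gold members missing from score table; scored 0", len(missing))
    return float(np.median([scores.get(g, 0.0) for g in gold]))


def rank_table(scores: pd.Series, count_scores: pd.Series | None = None) -> pd.DataFrame:
    """Rank genes by score, descending.

    Equal scores share the minimum rank; the listing order among ties is by
    count score (descending) then protein id.  Output columns: ``protein_id``,
    ``score``, ``rank``.
    """
    s = pd.Series(scores, dtype=float)
    cs = pd.Series(count_scores, dtype=float).reindex(s.index).fillna(0) \
        if count_scores is not None else pd.Series(0.0, index=s.index)
    df = pd.DataFrame({"protein_id": s.index, "score": s.to_numpy(), "_cs": cs.to_numpy()})
    df = df.sort_values(["score", "_cs", "protein_id"], ascending=[False, False, True],
                        kind="stable").reset_index(drop=True)
    # minimum rank among equal scores
    df["rank"] = df["score"].rank(method="min", ascending=False).astype(int)
    return df[["protein_id", "score", "rank"]]


def build_score_cards(
    screen_calls: Mapping[str, pd.DataFrame],
    weights: ScreenWeights | None = None,
    gold: set[str] | None = None,
    tails: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ScreenWeights]:
    """Assemble the master per-gene score table from consolidated screen calls.

    ``screen_calls`` maps screen_id to a consolidated hit-call frame
    (``protein_id``, ``z``, ``is_hit``); each screen's quantified universe is
    exactly the proteins in its frame.  If ``weights`` is None they are
    derived from ``gold`` via :func:`screen_information_weights` (uniform if
    no gold given).

    Returns the master table (one row per protein in the union universe, with
    per-screen ``z_<sid>``/``hit_<sid>``/``ns_<sid>`` columns, ``count_score``,
    ``aggregate_z``, ``weighted_score`` and the three ranks) and the weights
    used.
    """
    sids = list(screen_calls)
    tails = dict(tails or {})
    universe: set[str] = set()
    for df in screen_calls.values():
        universe |= set(df["protein_id"])
    index = sorted(universe)

    z_cols, hit_cols, ns_cols = {}, {}, {}
    hit_sets, universes = {}, {}
    for sid, df in screen_calls.items():
        z = df.set_index("protein_id")["z"]
        ns = normalize_screen_score(z, tail=tails.get(sid, "+"))
        hit_sets[sid] = set(df.loc[df["is_hit"], "protein_id"])
        universes[sid] = set(df["protein_id"])
        z_cols[sid] = z.reindex(index)
        hit_cols[sid] = pd.Series(np.isin(index, list(hit_sets[sid])), index=index)
        ns_cols[sid] = ns.reindex(index).fillna(0.0)  # not quantified -> 0

    if weights is None:
        if gold:
            weights = screen_information_weights(hit_sets, universes, gold)
        else:
            weights = ScreenWeights.uniform(sids)

    master = pd.DataFrame(index=pd.Index(index, name="protein_id"))
    for sid in sids:
        master[f"z_{sid}"] = z_cols[sid]
        master[f"hit_{sid}"] = hit_cols[sid]
        master[f"ns_{sid}"] = ns_cols[sid]
    hits_mat = master[[f"hit_{s}" for s in sids]].to_numpy(bool)
    ns_mat = master[[f"ns_{s}" for s in sids]].to_numpy(float)
    w = np.array([weights.weights[s] for s in sids])
    master["count_score"] = hits_mat.sum(axis=1)
    master["aggregate_z"] = ns_mat.sum(axis=1)
    master["weighted_score"] = ns_mat @ w

    for scheme in ("count_score", "aggregate_z", "weighted_score"):
        rt = rank_table(master[scheme], master["count_score"])
        master[f"rank_{scheme}"] = rt.set_index("protein_id")["rank"].reindex(index)
    return master.reset_index(), weights
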