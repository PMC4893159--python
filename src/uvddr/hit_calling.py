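"""Per-screen robust Z-scoring, directional hit calls, site rollup, S/TQ motif.

Each screen's log2-ratio distribution is standardized with a median/MAD
robust Z (``z = (x - median) / (1.4826 * MAD)``), which tolerates the heavy
tails typical of SILAC ratio distributions.  A protein is a *hit* when its Z
lies in the screen's damage-response tail at or beyond the threshold
(inclusive).  Which tail counts as the response is a per-screen policy: for
example proteins are recruited to CSB upon DNA damage (upper tail) while the
chromatin proteome both gains and loses proteins (both tails recorded, one
configured as the response).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_io import PTMSiteTable, SCREENS

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # makes MAD a consistent sigma estimate for Normal data

#: Default response tail per screen: "+" (increased/recruited), "-" (lost),
#: or "both".  The RNAi screen's response axis is the low-transcriber tail,
#: which is oriented to be positive by rnai_stats.
DEFAULT_TAILS: dict[str, str] = {
    "csb_interactome": "+",
    "rnapii_interactome": "+",
    "chromatin": "+",
    "ubiquitylome": "+",
    "phosphoproteome": "+",
    "rnai": "+",
}


class InsufficientDataError(ValueError):
    pass


@dataclass
class ScreenDirectionPolicy:
    """Which tail(s) count as the damage-response hit, per screen."""

    tails: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TAILS))

    def tail(self, screen_id: str) -> str:
        if screen_id not in self.tails:
            raise KeyError(f"screen {screen_id!r} has no direction policy")
        t = self.tails[screen_id]
        if t not in ("+", "-", "both"):
            raise ValueError(f"bad tail spec {t!r} for {screen_id}")
        return t


def robust_z(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Median/MAD robust Z-scores of ``values``.

    Falls back to the sample standard deviation when the MAD is zero; if that
    is also zero every Z is 0 and a warning is logged.  Requires at least
    three finite values.  The output median is exactly 0 and the scores are
    invariant under positive affine transforms of the input.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 3:
        raise InsufficientDataError(f"insufficient data: {len(s)} values (need >= 3)")
    x = s.to_numpy()
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    med = np.median(x)
    scale = MAD_SCALE * np.median(np.abs(x - med))
    if scale == 0.0:
        scale = float(np.std(x, ddof=1))
        if scale == 0.0:
            logger.warning("degenerate scale (all values equal); returning all-zero Z")
            return pd.Series(np.zeros(len(s)), index=s.index)
        logger.warning("MAD is 0; falling back to sample standard deviation")
    return pd.Series((x - med) / scale, index=s.index)


def call_hits(
    z: Mapping[str, float] | pd.Series,
    threshold: float,
    policy: ScreenDirectionPolicy,
    screen_id: str,
) -> pd.DataFrame:
    """Directional hit calls for one screen.

    Returns one row per protein (hit or not) with columns ``protein_id``,
    ``screen_id``, ``z``, ``direction`` (+1/-1, the sign of z), ``is_hit``.
    The threshold is inclusive: ``z`` exactly at the threshold is a hit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    tail = policy.tail(screen_id)
    zs = pd.Series(z, dtype=float)
    zv = zs.to_numpy()
    if tail == "+":
        is_hit = zv >= threshold
    elif tail == "-":
        is_hit = zv <= -threshold
    else:
        is_hit = np.abs(zv) >= threshold
    df = pd.DataFrame(
        {
            "protein_id": zs.index,
            "screen_id": screen_id,
            "z": zv,
            "direction": np.where(zv >= 0, 1, -1),
            "is_hit": is_hit,
        }
    )
    return df.sort_values("protein_id", kind="stable").reset_index(drop=True)


def merge_condition_calls(calls: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-condition calls (e.g. +/-MG132) into one screen-level call.

    A protein is a hit if it passes in *either* condition; its screen-level z
    is the condition entry with maximum \\|z|.  The ``conditions_hit`` column
    records which condition indices passed.
    """
    if not calls:
        raise ValueError("no condition calls to merge")
    if len(calls) == 1:
        out = calls[0].copy()
        out["conditions_hit"] = np.where(out["is_hit"], "0", "")
        return out
    tagged = []
    for i, c in enumerate(calls):
        c = c.copy()
        c["_cond"] = i
        tagged.append(c)
    allc = pd.concat(tagged, ignore_index=True)
    allc["_abs"] = allc["z"].abs()
    # stable sort: strongest |z| last; earlier condition wins exact ties
    allc = allc.sort_values(["_abs", "_cond"], ascending=[True, False], kind="stable")
    best = allc.drop_duplicates("protein_id", keep="last").set_index("protein_id")
    grp = allc.groupby("protein_id")
    any_hit = grp["is_hit"].any()
    conds = grp.apply(
        lambda g: ",".join(str(i) for i in sorted(g.loc[g["is_hit"], "_cond"])),
        include_groups=False,
    )
    out = pd.DataFrame(
        {
            "protein_id": best.index,
            "screen_id": best["screen_id"],
            "z": best["z"],
            "direction": best["direction"],
            "is_hit": any_hit.reindex(best.index),
            "conditions_hit": conds.reindex(best.index).fillna(""),
        }
    ).reset_index(drop=True)
    return out.sort_values("protein_id", kind="stable").reset_index(drop=True)


def rollup_sites(sites: PTMSiteTable, site_z: pd.Series) -> pd.DataFrame:
    """Roll site-level Z-scores up to protein level.

    The protein-level Z is the site Z with maximum \\|z| (the strongest
    modification response); exact ties break toward the smaller residue
    position.  ``site_z`` must be indexed like ``sites.data`` (one z per
    site row, computed by :func:`robust_z` over all sites of the same
    modification).  One output row per distinct protein.
    """
    d = sites.data.copy()
    d["z"] = pd.Series(site_z, dtype=float).reindex(d.index).to_numpy()
    if d["z"].isna().any():
        raise ValueError("site_z does not cover all site rows")
    d["_abs"] = d["z"].abs()
    # strongest |z| first; smaller position wins ties
    d = d.sort_values(["protein_id", "_abs", "position"], ascending=[True, False, True], kind="stable")
    best = d.drop_duplicates("protein_id", keep="first")
    out = pd.DataFrame(
        {
            "protein_id": best["protein_id"],
            "z": best["z"],
            "best_site": [f"{r}{p}" for r, p in zip(best["residue"], best["position"])],
            "best_position": best["position"],
        }
    ).reset_index(drop=True)
    return out.sort_values("protein_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# S/TQ motif (ATM/ATR consensus)
# ---------------------------------------------------------------------------

def classify_stq(window: str) -> bool:
    """True iff the window centre is S or T immediately followed by Q.

    ``window`` is an odd-length (>= 3) flanking sequence centred on the
    phospho-residue.  S/T-Q is the ATM/ATR kinase consensus motif.
    """
    w = window.strip().upper()
    if len(w) < 3 or len(w) % 2 == 0:
        raise ValueError(f"window must have odd length >= 3, got {window!r}")
    c = len(w) // 2
    return w[c] in "ST" and w[c + 1] == "Q"


def count_stq(
    sites: PTMSiteTable,
    increased: Iterable[tuple[str, int]] | None = None,
) -> tuple[int, int]:
    """Count S/TQ phospho-sites, total and UV-increased.

    Counts unique ``(protein_id, position)`` phospho-sites whose window
    matches the S/T-Q consensus; ``increased`` is the set of sites called in
    the UV-increased tail (empty -> second count is 0).
    """
    if sites.modification != "phospho":
        raise ValueError("count_stq applies to phospho site tables")
    d = sites.data.drop_duplicates(subset=["protein_id", "position"])
    is_stq = d["window"].map(classify_stq)
    n_total = int(is_stq.sum())
    if increased is None:
        return n_total, 0
    inc = set(increased)
    keys = list(zip(d["protein_id"], d["position"]))
    n_up = int(sum(1 for k, s in zip(keys, is_stq) if s and k in inc))
    return n_total, n_up
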