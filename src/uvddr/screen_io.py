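"""Data model and readers/writers for screen, PTM, RNAi, category and network inputs.

All tabular formats are tab-separated UTF-8 with a header row.  Positions are
1-based (so a ubiquitylated lysine written ``K163`` is residue 163 of the
protein).  The canonical identifier space is the trimmed, upper-cased gene
symbol; a user-supplied alias table maps known synonyms (e.g. ``ERCC6`` ->
``CSB``) before casing, because screens routinely mix gene symbols and
historical protein names.

A protein absent from a screen is *not quantified* — represented by absence,
never imputed as ratio 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six screens of the study design.  ``csb_interactome`` and ``chromatin``
#: each have +/-MG132 conditions that are merged into a single screen-level
#: call before integration; ``rnapii_interactome`` was run +MG132 only.
SCREENS = (
    "csb_interactome",
    "rnapii_interactome",
    "chromatin",
    "ubiquitylome",
    "phosphoproteome",
    "rnai",
)

PHOSPHO_RESIDUES = frozenset("STY")
UBIQUITIN_RESIDUES = frozenset("K")
CONTROL_TYPES = ("non_targeting", "risc_free", "positive_control")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


# ---------------------------------------------------------------------------
# identifier harmonization
# ---------------------------------------------------------------------------

def harmonize_id(raw_id: str, aliases: Mapping[str, str] | None = None) -> str:
    """Return the canonical protein identifier for ``raw_id``.

    Trims whitespace, applies the optional alias table (matched
    case-insensitively), and upper-cases the result.  Idempotent as long as
    the alias table does not map a canonical name onto another alias.

    Raises
    ------
    ValueError
        If the identifier is empty after trimming.
    """
    s = str(raw_id).strip()
    if not s:
        raise ValueError("empty protein identifier")
    if aliases:
        upper_aliases = {k.strip().upper(): v.strip().upper() for k, v in aliases.items()}
        s = upper_aliases.get(s.upper(), s.upper())
    return s.upper()


# ---------------------------------------------------------------------------
# parse accounting
# ---------------------------------------------------------------------------

@dataclass
class ParseReport:
    """Row accounting for one parsed file.

    ``rows_in == rows_kept + rows_rejected`` always holds; rows merged away by
    duplicate collapsing are counted inside ``rows_rejected`` and broken out
    in ``duplicates_collapsed``.
    """

    path: str
    rows_in: int = 0
    rows_kept: int = 0
    rows_invalid: int = 0
    duplicates_collapsed: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return self.rows_invalid + self.duplicates_collapsed

    def log(self) -> None:
        logger.info(
            "%s: %d rows read, %d kept, %d invalid, %d duplicates collapsed",
            self.path, self.rows_in, self.rows_kept, self.rows_invalid,
            self.duplicates_collapsed,
        )
        for m in self.messages:
            logger.warning("%s: %s", self.path, m)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Condition:
    """Treatment flags for one screen table."""

    uv: bool = True
    mg132: bool = False

    def label(self) -> str:
        return ("uv" if self.uv else "mock") + ("+mg132" if self.mg132 else "-mg132")


@dataclass
class ScreenTable:
    """One proteomic screen's protein-level log2(UV/control) SILAC ratios.

    ``data`` has one row per protein with columns ``protein_id``,
    ``log2_ratio`` and optionally ``ibaq`` (absolute-abundance proxy, >= 0).
    """

    screen_id: str
    condition: Condition
    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if d["protein_id"].duplicated().any():
            raise ValueError(f"{self.screen_id}: duplicate protein_ids")
        if len(d) and not np.isfinite(d["log2_ratio"].to_numpy(float)).all():
            raise ValueError(f"{self.screen_id}: non-finite log2_ratio")
        if "ibaq" in d.columns:
            ib = d["ibaq"].to_numpy(float)
            if np.nanmin(ib, initial=0.0) < 0:
                raise ValueError(f"{self.screen_id}: negative ibaq")

    @property
    def ratios(self) -> pd.Series:
        """log2 ratios indexed by protein_id."""
        return self.data.set_index("protein_id")["log2_ratio"]

    def proteins(self) -> set[str]:
        return set(self.data["protein_id"])


@dataclass
class PTMSiteTable:
    """Site-level modification measurements (ubiquitylome or phosphoproteome).

    ``data`` columns: ``protein_id``, ``residue``, ``position`` (1-based),
    ``window`` (odd-length flanking sequence centred on the site),
    ``log2_ratio``.  ``(protein_id, position)`` is unique within one
    modification.
    """

    modification: str  # "phospho" | "ubiquitin"
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.modification not in ("phospho", "ubiquitin"):
            raise ValueError(f"unknown modification {self.modification!r}")
        d = self.data
        if d.duplicated(subset=["protein_id", "position"]).any():
            raise ValueError("duplicate (protein_id, position) site")
        if len(d):
            if (d["position"] < 1).any():
                raise ValueError("positions must be 1-based")
            allowed = PHOSPHO_RESIDUES if self.modification == "phospho" else UBIQUITIN_RESIDUES
            if not d["residue"].isin(allowed).all():
                raise ValueError(f"residue inconsistent with {self.modification}")

    def sites(self) -> set[tuple[str, int]]:
        return set(zip(self.data["protein_id"], self.data["position"]))


@dataclass
class RNAiWellProfile:
    """Per-well nascent-transcription readout of the RNAi screen.

    Either ``cells`` (per-cell EU fluorescence intensities, >= 0) or a
    precomputed summary (``n_cells``, ``median_intensity``, ``fraction_low``)
    is present.  ``control_type`` is empty for gene-targeting wells.
    """

    plate_id: str
    well_id: str
    target_gene: str
    uv_treated: bool = True
    control_type: str = ""
    cells: np.ndarray | None = None
    n_cells: int | None = None
    median_intensity: float | None = None
    fraction_low: float | None = None

    def __post_init__(self) -> None:
        if self.control_type and self.control_type not in CONTROL_TYPES:
            raise ValueError(f"unknown control_type {self.control_type!r}")
        if self.cells is not None:
            self.cells = np.asarray(self.cells, dtype=float)
            if len(self.cells) and self.cells.min() < 0:
                raise ValueError("negative cell intensity")
            self.n_cells = len(self.cells)
        if self.n_cells is not None and self.n_cells < 0:
            raise ValueError("n_cells < 0")
        if self.fraction_low is not None and not 0.0 <= self.fraction_low <= 1.0:
            raise ValueError("fraction_low outside [0,1]")

    @property
    def is_negative_control(self) -> bool:
        return self.control_type in ("non_targeting", "risc_free")


@dataclass
class CategorySet:
    """Named gene categories (pathways, complexes, the training category).

    Members outside ``universe`` are dropped on construction with a logged
    count; categories left empty are removed.
    """

    categories: dict[str, tuple[str, set[str]]]  # id -> (display name, members)
    universe: set[str]

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, set[str]]] = {}
        dropped_members = 0
        for cid, (name, members) in self.categories.items():
            kept = set(members) & self.universe
            dropped_members += len(set(members)) - len(kept)
            if kept:
                cleaned[cid] = (name, kept)
            else:
                logger.warning("category %s empty after universe restriction; dropped", cid)
        if dropped_members:
            logger.info("dropped %d category members outside the universe", dropped_members)
        self.categories = cleaned

    def members(self, cid: str) -> set[str]:
        return self.categories[cid][1]

    def __contains__(self, cid: str) -> bool:
        return cid in self.categories

    def __len__(self) -> int:
        return len(self.categories)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_screen_table(
    path: str | Path,
    screen_id: str,
    condition: Condition | None = None,
    *,
    protein_col: str = "protein_id",
    ratio_col: str = "log2_ratio",
    ibaq_col: str = "ibaq",
    aliases: Mapping[str, str] | None = None,
    collapse: str = "max_abs",
) -> tuple[ScreenTable, ParseReport]:
    """Read one screen's TSV into a validated :class:`ScreenTable`.

    Duplicate protein rows are collapsed by ``collapse``: ``"max_abs"`` keeps
    the row with the largest \\|log2_ratio| (strongest signal), ``"mean"``
    averages.  Non-numeric ratio rows are dropped and counted in the report.
    """
    if collapse not in ("max_abs", "mean"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (protein_col, ratio_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    report = ParseReport(path=str(path), rows_in=len(df))
    if len(df) == 0:
        report.messages.append("file has a header but no rows")

    ratios = pd.to_numeric(df[ratio_col], errors="coerce")
    bad = ~np.isfinite(ratios)
    if bad.any():
        report.rows_invalid += int(bad.sum())
        report.messages.append(f"{int(bad.sum())} rows with non-numeric/non-finite ratio dropped")
    df = df.loc[~bad].copy()
    df["log2_ratio"] = ratios[~bad]
    df["protein_id"] = [harmonize_id(p, aliases) for p in df[protein_col]]
    if ibaq_col in df.columns:
        df["ibaq"] = pd.to_numeric(df[ibaq_col], errors="coerce")

    cols = ["protein_id", "log2_ratio"] + (["ibaq"] if "ibaq" in df.columns else [])
    df = df[cols]
    dups = df["protein_id"].duplicated(keep=False)
    if dups.any():
        n_before = len(df)
        if collapse == "max_abs":
            df = (
                df.reindex(df["log2_ratio"].abs().sort_values(kind="stable").index)
                .drop_duplicates("protein_id", keep="last")
            )
        else:
            df = df.groupby("protein_id", as_index=False).mean(numeric_only=True)
        report.duplicates_collapsed = n_before - len(df)
    df = df.sort_values("protein_id", kind="stable").reset_index(drop=True)
    report.rows_kept = len(df)
    report.log()
    table = ScreenTable(screen_id=screen_id, condition=condition or Condition(), data=df)
    return table, report


def write_screen_table(table: ScreenTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


_SITE_TOKEN_OK = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _parse_site_token(token: str) -> tuple[str, int]:
    """``"K163"`` -> ``("K", 163)``."""
    token = token.strip()
    if len(token) < 2 or token[0].upper() not in _SITE_TOKEN_OK or not token[1:].isdigit():
        raise ValueError(f"bad site token {token!r}")
    return token[0].upper(), int(token[1:])


def read_ptm_table(
    path: str | Path,
    modification: str,
    *,
    aliases: Mapping[str, str] | None = None,
) -> tuple[PTMSiteTable, ParseReport]:
    """Read a site-level PTM TSV.

    Accepts either explicit ``residue`` + ``position`` columns or a combined
    ``site`` token column (``K163``).  Rows whose window centre does not match
    the residue, whose residue is inconsistent with the modification, or whose
    site token is malformed are rejected and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "protein_id" not in df.columns or "window" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'protein_id' or 'window'")
    has_site = "site" in df.columns
    if not has_site and not {"residue", "position"} <= set(df.columns):
        raise FormatError(f"{path}: need 'site' or 'residue'+'position' columns")
    if "log2_ratio" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'log2_ratio'")

    allowed = PHOSPHO_RESIDUES if modification == "phospho" else UBIQUITIN_RESIDUES
    report = ParseReport(path=str(path), rows_in=len(df))
    rows = []
    for rec in df.itertuples(index=False):
        try:
            pid = harmonize_id(rec.protein_id, aliases)
            if has_site:
                residue, position = _parse_site_token(rec.site)
            else:
                residue, position = rec.residue.strip().upper(), int(rec.position)
            window = rec.window.strip().upper()
            ratio = float(rec.log2_ratio)
            if position < 1:
                raise ValueError("position < 1")
            if len(window) < 3 or len(window) % 2 == 0:
                raise ValueError("window must have odd length >= 3")
            if window[len(window) // 2] != residue:
                raise ValueError("window centre does not match residue")
            if residue not in allowed:
                raise ValueError(f"residue {residue} invalid for {modification}")
            if not np.isfinite(ratio):
                raise ValueError("non-finite ratio")
        except (ValueError, AttributeError) as exc:
            report.rows_invalid += 1
            report.messages.append(f"row rejected: {exc}")
            continue
        rows.append((pid, residue, position, window, ratio))

    out = pd.DataFrame(rows, columns=["protein_id", "residue", "position", "window", "log2_ratio"])
    n_before = len(out)
    out = out.drop_duplicates(subset=["protein_id", "position"], keep="first")
    report.duplicates_collapsed = n_before - len(out)
    out = out.sort_values(["protein_id", "position"], kind="stable").reset_index(drop=True)
    report.rows_kept = len(out)
    report.log()
    return PTMSiteTable(modification=modification, data=out), report


def write_ptm_table(table: PTMSiteTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_categories(
    path: str | Path,
    universe: Iterable[str] | None = None,
    *,
    aliases: Mapping[str, str] | None = None,
) -> CategorySet:
    """Read GMT gene sets (``id <TAB> description <TAB> member...``).

    If ``universe`` is None it is inferred as the union of all members.
    Duplicate members within a line are deduplicated; members outside the
    universe are dropped (logged); empty categories are removed.
    """
    cats: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line with fewer than 3 fields: {line[:50]!r}")
            cid, desc = parts[0].strip(), parts[1].strip()
            members = {harmonize_id(m, aliases) for m in parts[2:] if m.strip()}
            cats[cid] = (desc, members)
    if universe is None:
        universe = set().union(*(m for _, m in cats.values())) if cats else set()
    else:
        universe = {harmonize_id(u, aliases) for u in universe}
    return CategorySet(categories=cats, universe=set(universe))


def write_categories(catset: CategorySet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, (name, members) in sorted(catset.categories.items()):
            fh.write("\t".join([cid, name, *sorted(members)]) + "\n")


def read_network(path: str | Path, *, aliases: Mapping[str, str] | None = None) -> nx.Graph:
    """Read a two-column edge TSV into an undirected, deduplicated graph.

    Self-loops are discarded.  An optional third column is stored as the edge
    ``source`` attribute.
    """
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge file needs at least two columns")
    for rec in df.itertuples(index=False):
        a = harmonize_id(rec[0], aliases)
        b = harmonize_id(rec[1], aliases)
        if a == b:
            continue
        attrs = {"source": rec[2]} if len(rec) > 2 and isinstance(rec[2], str) else {}
        g.add_edge(a, b, **attrs)
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"protein_a": min(a, b), "protein_b": max(a, b), "source": d.get("source", "")}
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "source"]).sort_values(
        ["protein_a", "protein_b"]
    ).to_csv(path, sep="\t", index=False)


def read_rnai_wells(path: str | Path, *, aliases: Mapping[str, str] | None = None) -> list[RNAiWellProfile]:
    """Read the RNAi wells TSV.

    Columns: ``plate_id``, ``well_id``, ``target_gene``, ``control_type``,
    ``uv``, then either ``intensities`` (semicolon-separated per-cell values)
    or the summary columns ``n_cells``, ``median_intensity``, ``fraction_low``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"plate_id", "well_id", "target_gene", "uv"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: missing mandatory columns {sorted(needed - set(df.columns))}")
    wells = []
    for rec in df.itertuples(index=False):
        ctl = getattr(rec, "control_type", "") or ""
        if isinstance(ctl, float):  # NaN from pandas
            ctl = ""
        gene = rec.target_gene if ctl else harmonize_id(rec.target_gene, aliases)
        kw: dict = {}
        raw = getattr(rec, "intensities", None)
        if isinstance(raw, str) and raw:
            kw["cells"] = np.fromiter((float(x) for x in raw.split(";")), dtype=float)
        else:
            for col in ("n_cells", "median_intensity", "fraction_low"):
                v = getattr(rec, col, None)
                if isinstance(v, str) and v:
                    kw[col] = int(v) if col == "n_cells" else float(v)
        wells.append(
            RNAiWellProfile(
                plate_id=rec.plate_id,
                well_id=rec.well_id,
                target_gene=gene,
                uv_treated=str(rec.uv).strip().lower() in ("1", "true", "yes", "uv"),
                control_type=ctl,
                **kw,
            )
        )
    return wells


def write_rnai_wells(wells: Sequence[RNAiWellProfile], path: str | Path, *, decimals: int = 2) -> None:
    rows = []
    for w in wells:
        row = {
            "plate_id": w.plate_id,
            "well_id": w.well_id,
            "target_gene": w.target_gene,
            "control_type": w.control_type,
            "uv": int(w.uv_treated),
            "intensities": "",
            "n_cells": "" if w.n_cells is None else w.n_cells,
            "median_intensity": "" if w.median_intensity is None else w.median_intensity,
            "fraction_low": "" if w.fraction_low is None else w.fraction_low,
        }
        if w.cells is not None:
            row["intensities"] = ";".join(f"{x:.{decimals}f}" for x in w.cells)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
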