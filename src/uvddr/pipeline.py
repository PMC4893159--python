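"""End-to-end orchestration and per-protein report export.

``run_bundle`` takes an in-memory :class:`~uvddr.synthetic_data.Bundle` (or
any equivalently shaped inputs via ``run_screens``) through hit calling,
RNAi scoring, integration, and enrichment, returning a
:class:`PipelineResult`.  ``write_outputs`` materializes the result as TSV/
JSON files together with a machine-readable run manifest (parameters, input
row counts, package version) so a run can be reproduced bit-exactly.
``build_protein_report`` consolidates everything known about one protein —
the file-export analogue of a per-gene database page.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .enrichment import category_screen_matrix, enrich_categories
from .hit_calling import (
    ScreenDirectionPolicy,
    call_hits,
    count_stq,
    merge_condition_calls,
    robust_z,
    rollup_sites,
)
from .integration import ScreenWeights, build_score_cards
from .rnai_stats import as_screen_calls, gene_level_calls, score_wells
from .screen_io import CategorySet, PTMSiteTable, RNAiWellProfile, ScreenTable
from .synthetic_data import _SCREEN_OF_MOD, Bundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    z_threshold: float = 2.0
    rnai_low_quantile: float = 25.0
    rnai_min_cells: int = 50
    min_category_size: int = 3
    max_category_size: int = 2000
    enrichment_top_n: int = 300  # high-scoring set tested for enrichment
    policy: ScreenDirectionPolicy = field(default_factory=ScreenDirectionPolicy)

    def to_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "rnai_low_quantile": self.rnai_low_quantile,
            "rnai_min_cells": self.rnai_min_cells,
            "min_category_size": self.min_category_size,
            "max_category_size": self.max_category_size,
            "enrichment_top_n": self.enrichment_top_n,
            "tails": dict(self.policy.tails),
        }


@dataclass
class PipelineResult:
    screen_calls: dict[str, pd.DataFrame]   # consolidated, one frame per screen
    site_calls: dict[str, pd.DataFrame]     # per-modification site-level calls
    best_sites: dict[str, pd.DataFrame]     # protein -> best site per modification
    rnai_gene_table: pd.DataFrame
    master: pd.DataFrame
    weights: ScreenWeights
    enrichment: pd.DataFrame
    coverage_matrix: pd.DataFrame
    stq_counts: tuple[int, int]
    params: PipelineParams


def run_screens(
    ms_screens: Mapping[str, list[ScreenTable]],
    ptm_tables: Mapping[str, PTMSiteTable],
    rnai_wells: list[RNAiWellProfile],
    categories: CategorySet,
    gold_category: str | None = "TCR",
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full integration over explicit screen inputs.

    ``ms_screens`` maps screen_id to its per-condition ratio tables (merged
    with the hit-in-either-condition rule); ``ptm_tables`` maps modification
    to its site table (site Z-scores rolled up to protein level by max |z|);
    RNAi wells are scored per plate and aggregated to gene level.  Weights
    come from the ``gold_category`` in ``categories`` (uniform when absent).
    """
    params = params or PipelineParams()
    thr = params.z_threshold
    policy = params.policy
    screen_calls: dict[str, pd.DataFrame] = {}

    for sid, tables in ms_screens.items():
        per_cond = []
        for t in tables:
            z = robust_z(t.ratios)
            per_cond.append(call_hits(z, thr, policy, sid))
        screen_calls[sid] = merge_condition_calls(per_cond)
        logger.info("screen %s: %d proteins, %d hits", sid,
                    len(screen_calls[sid]), int(screen_calls[sid]["is_hit"].sum()))

    site_calls: dict[str, pd.DataFrame] = {}
    best_sites: dict[str, pd.DataFrame] = {}
    for mod, table in ptm_tables.items():
        sid = _SCREEN_OF_MOD[mod]
        site_z = robust_z(table.data["log2_ratio"])
        sc = table.data[["protein_id", "residue", "position"]].copy()
        sc["z"] = site_z.to_numpy()
        sc["is_hit"] = site_z.to_numpy() >= thr  # UV-increased tail
        site_calls[mod] = sc
        prot = rollup_sites(table, site_z)
        best_sites[mod] = prot[["protein_id", "best_site"]]
        calls = call_hits(prot.set_index("protein_id")["z"], thr, policy, sid)
        screen_calls[sid] = calls
        logger.info("screen %s: %d proteins, %d hits (from %d sites)", sid,
                    len(calls), int(calls["is_hit"].sum()), len(table.data))

    stats = score_wells(rnai_wells, low_quantile=params.rnai_low_quantile,
                        min_cells=params.rnai_min_cells, z_threshold=thr)
    gene_table = gene_level_calls(stats, z_threshold=thr)
    screen_calls["rnai"] = as_screen_calls(gene_table, z_threshold=thr)
    logger.info("screen rnai: %d genes, %d low-transcriber hits",
                len(gene_table), int((gene_table["call"] == "low").sum()))

    gold = set(categories.members(gold_category)) \
        if gold_category and gold_category in categories else None
    master, weights = build_score_cards(screen_calls, gold=gold,
                                        tails=policy.tails)

    top = master.nlargest(params.enrichment_top_n, "weighted_score",
                          keep="first")["protein_id"]
    cat_universe = CategorySet(categories=dict(categories.categories),
                               universe=set(master["protein_id"]))
    enrichment = enrich_categories(set(top), cat_universe,
                                   min_size=params.min_category_size,
                                   max_size=params.max_category_size)
    hit_sets = {sid: set(df.loc[df["is_hit"], "protein_id"])
                for sid, df in screen_calls.items()}
    coverage = category_screen_matrix(cat_universe, hit_sets)

    stq = (0, 0)
    if "phospho" in ptm_tables:
        inc = site_calls["phospho"]
        inc_sites = set(zip(inc.loc[inc["is_hit"], "protein_id"],
                            inc.loc[inc["is_hit"], "position"]))
        stq = count_stq(ptm_tables["phospho"], inc_sites)

    return PipelineResult(
        screen_calls=screen_calls, site_calls=site_calls, best_sites=best_sites,
        rnai_gene_table=gene_table, master=master, weights=weights,
        enrichment=enrichment, coverage_matrix=coverage, stq_counts=stq,
        params=params,
    )


def run_bundle(bundle: Bundle, params: PipelineParams | None = None,
               gold_category: str | None = "TCR") -> PipelineResult:
    """Convenience wrapper: run the pipeline on a synthetic bundle."""
    return run_screens(bundle.screens, bundle.ptm, bundle.rnai_wells,
                       bundle.categories, gold_category=gold_category, params=params)


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------

def _df_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write hit calls, master score table, enrichment tables and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = pd.concat(result.screen_calls.values(), ignore_index=True)
    calls.to_csv(outdir / "hit_calls.tsv", sep="\t", index=False)
    for mod, bs in result.best_sites.items():
        bs.to_csv(outdir / f"best_sites_{mod}.tsv", sep="\t", index=False)
    result.rnai_gene_table.to_csv(outdir / "rnai_genes.tsv", sep="\t", index=False)
    result.master.to_csv(outdir / "master_scores.tsv", sep="\t", index=False)
    result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    result.coverage_matrix.to_csv(outdir / "category_screen_matrix.tsv",
                                  sep="\t", index=False)
    manifest = {
        "package": "uvddr",
        "version": __version__,
        "params": result.params.to_dict(),
        "weights": result.weights.weights,
        "raw_weights": result.weights.raw,
        "stq_total": result.stq_counts[0],
        "stq_uv_increased": result.stq_counts[1],
        "tables": {
            "master_scores": {"rows": len(result.master), "sha256_16": _df_hash(result.master)},
            "hit_calls": {"rows": len(calls), "sha256_16": _df_hash(calls)},
            "enrichment": {"rows": len(result.enrichment)},
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def build_protein_report(protein_id: str, result: PipelineResult,
                         categories: CategorySet | None = None) -> dict:
    """Consolidated per-protein evidence report (JSON-serializable dict).

    Unknown proteins yield an explicit "not quantified in any screen" report
    rather than an error.  Every field is copied from stage outputs; nothing
    is recomputed here.
    """
    pid = protein_id.strip().upper()
    master = result.master.set_index("protein_id")
    report: dict = {"protein_id": pid, "screens": {}, "scores": {}, "categories": []}
    quantified = False
    for sid, calls in result.screen_calls.items():
        row = calls.loc[calls["protein_id"] == pid]
        if len(row):
            quantified = True
            rec = {"z": float(row["z"].iloc[0]), "is_hit": bool(row["is_hit"].iloc[0])}
            for mod, sid_of in ((m, _SCREEN_OF_MOD[m]) for m in result.best_sites):
                if sid_of == sid:
                    bs = result.best_sites[mod]
                    hit = bs.loc[bs["protein_id"] == pid, "best_site"]
                    if len(hit):
                        rec["best_site"] = hit.iloc[0]
            report["screens"][sid] = rec
        else:
            report["screens"][sid] = {"quantified": False}
    report["quantified_in_any_screen"] = quantified
    if pid in master.index:
        m = master.loc[pid]
        for scheme in ("count_score", "aggregate_z", "weighted_score"):
            report["scores"][scheme] = {
                "score": float(m[scheme]),
                "rank": int(m[f"rank_{scheme}"]),
            }
    else:
        report["scores"] = {s: {"score": 0.0, "rank": None}
                            for s in ("count_score", "aggregate_z", "weighted_score")}
    if categories is not None:
        enr = result.enrichment.set_index("category_id") if len(result.enrichment) else None
        for cid, (name, members) in sorted(categories.categories.items()):
            if pid in members:
                entry = {"category_id": cid, "name": name}
                if enr is not None and cid in enr.index:
                    entry["p_adj"] = float(enr.loc[cid, "p_adj"])
                report["categories"].append(entry)
    return report


def write_protein_report(report: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"report_{report['protein_id']}.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    rows = [{"screen_id": sid, **rec} for sid, rec in report["screens"].items()]
    pd.DataFrame(rows).to_csv(outdir / f"report_{report['protein_id']}.tsv",
                              sep="\t", index=False)
    return path
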