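"""Seeded generator of a full multi-screen bundle with planted ground truth.

The generator emulates the statistical structure the integration analysis
assumes: most proteins are unchanged in every screen, a minority of *true
factors* respond in a screen-dependent, partially overlapping way, and a
curated subset of the true factors forms the gold-standard training
category.  Concretely:

* **SILAC screens** (CSB interactome ±MG132, RNAPII interactome +MG132,
  chromatin ±MG132): background log2 ratios ~ Normal(0, noise_sd); each true
  factor responds in a screen with that screen's sensitivity, adding
  Normal(effect_size, noise_sd/2) in the response (positive) direction.
  Screen sensitivities are heterogeneous by default so the training-category
  weighting has real signal to exploit.
* **PTM tables** (ubiquitylome, phosphoproteome): 1-5 sites per covered
  protein; responding proteins carry one shifted site.  Phospho residue
  composition is S:T:Y = 86:13:1, and 15% of phospho windows carry the
  S/T-Q (ATM/ATR consensus) motif.
* **RNAi wells**: per-cell EU intensities from a two-component log-normal
  mixture; the low-component weight is the baseline fraction for control and
  background wells and the (larger) knockdown fraction for planted
  low-transcriber genes.  Plates carry non-targeting, RISC-free and positive
  control wells.

All randomness flows from one integer seed through a fixed
``numpy.random.SeedSequence`` spawning order, so the bundle is byte-identical
across runs and individual tables are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .screen_io import (
    CategorySet,
    Condition,
    PTMSiteTable,
    RNAiWellProfile,
    ScreenTable,
    write_categories,
    write_ptm_table,
    write_rnai_wells,
    write_screen_table,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
MS_SCREEN_CONDITIONS: dict[str, tuple[Condition, ...]] = {
    "csb_interactome": (Condition(uv=True, mg132=False), Condition(uv=True, mg132=True)),
    "rnapii_interactome": (Condition(uv=True, mg132=True),),
    "chromatin": (Condition(uv=True, mg132=False), Condition(uv=True, mg132=True)),
}
PTM_SCREENS = ("ubiquitylome", "phosphoproteome")

DEFAULT_SENSITIVITY = {
    "csb_interactome": 0.7,
    "rnapii_interactome": 0.6,
    "chromatin": 0.4,
    "ubiquitylome": 0.5,
    "phosphoproteome": 0.5,
    "rnai": 0.35,
}


@dataclass
class RNAiSimConfig:
    """RNAi-arm parameters.

    Intensities are exp(Normal) on an arbitrary fluorescence scale; the low
    and high components are separated by 2 log units (4 log-SDs), matching a
    clearly bimodal post-UV EU profile.  Plate layout: 320 test wells plus 16
    non-targeting, 16 RISC-free and 8 positive-control wells.
    """

    cells_per_well: int = 300
    log_low_mean: float = 5.0
    log_high_mean: float = 7.0
    log_sd: float = 0.5
    baseline_low_fraction: float = 0.15
    knockdown_low_fraction: float = 0.6
    test_wells_per_plate: int = 320
    non_targeting_per_plate: int = 16
    risc_free_per_plate: int = 16
    positive_controls_per_plate: int = 8


@dataclass
class SimulationConfig:
    n_proteins: int = 5000
    n_true_factors: int = 100
    sensitivity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    effect_size: float = 2.0
    noise_sd: float = 0.5
    gold_fraction: float = 0.3
    ms_coverage: float = 0.9      # background quantification rate in MS screens
    ptm_coverage: float = 0.6     # background site coverage in PTM screens
    sites_min: int = 1
    sites_max: int = 5
    stq_rate: float = 0.15        # S/TQ fraction among phospho sites
    phospho_residue_probs: tuple[float, float, float] = (0.86, 0.13, 0.01)  # S, T, Y
    window_flank: int = 3         # windows of length 2*flank+1
    n_random_categories: int = 25
    spike_in_names: tuple[str, ...] = ()
    rnai: RNAiSimConfig = field(default_factory=RNAiSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_true_factors <= self.n_proteins:
            raise ValueError("n_true_factors must lie in [0, n_proteins]")
        for sid, p in self.sensitivity.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sensitivity[{sid}] outside [0,1]")
        for name in ("noise_sd",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rnai.log_sd <= 0:
            raise ValueError("rnai.log_sd must be > 0")
        if not 0.0 <= self.gold_fraction <= 1.0:
            raise ValueError("gold_fraction outside [0,1]")
        for f in ("baseline_low_fraction", "knockdown_low_fraction"):
            if not 0.0 <= getattr(self.rnai, f) <= 1.0:
                raise ValueError(f"rnai.{f} outside [0,1]")
        if not 1 <= self.sites_min <= self.sites_max:
            raise ValueError("need 1 <= sites_min <= sites_max")
        if abs(sum(self.phospho_residue_probs) - 1.0) > 1e-9:
            raise ValueError("phospho_residue_probs must sum to 1")
        if len(self.spike_in_names) > self.n_proteins:
            raise ValueError("more spike-in names than proteins")


@dataclass
class GroundTruth:
    true_factors: set[str]
    responders: dict[str, set[str]]  # screen_id -> responding true factors
    gold: set[str]

    def __post_init__(self) -> None:
        assert self.gold <= self.true_factors or not self.true_factors
        for sid, r in self.responders.items():
            assert r <= self.true_factors, sid


@dataclass
class Bundle:
    """One complete synthetic study: five SILAC tables, two PTM tables,
    RNAi wells, categories (with the gold training category ``TCR``) and the
    planted ground truth."""

    screens: dict[str, list[ScreenTable]]
    ptm: dict[str, PTMSiteTable]
    rnai_wells: list[RNAiWellProfile]
    categories: CategorySet
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, tables in self.screens.items():
            for t in tables:
                write_screen_table(t, outdir / f"{sid}.{t.condition.label()}.tsv")
        for mod, table in self.ptm.items():
            write_ptm_table(table, outdir / f"{_SCREEN_OF_MOD[mod]}.tsv")
        write_rnai_wells(self.rnai_wells, outdir / "rnai_wells.tsv")
        write_categories(self.categories, outdir / "categories.gmt")
        truth_rows = [
            {"protein_id": p,
             "is_gold": p in self.truth.gold,
             **{f"responds_{sid}": p in r for sid, r in sorted(self.truth.responders.items())}}
            for p in sorted(self.truth.true_factors)
        ]
        pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _protein_ids(config: SimulationConfig) -> list[str]:
    ids = [f"P{i + 1:06d}" for i in range(config.n_proteins)]
    for i, name in enumerate(config.spike_in_names):
        ids[i] = name.upper()
    return ids


def _windows(rng: np.random.Generator, centers: np.ndarray, flank: int,
             stq: np.ndarray | None) -> list[str]:
    """Random flanking windows; ``stq`` forces/forbids Q at centre+1."""
    n = len(centers)
    mat = rng.choice(AMINO_ACIDS, size=(n, 2 * flank + 1))
    mat[:, flank] = centers
    if stq is not None:
        non_q = AMINO_ACIDS[AMINO_ACIDS != "Q"]
        mat[:, flank + 1] = np.where(stq, "Q", rng.choice(non_q, size=n))
    return ["".join(row) for row in mat]


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Generate the full multi-screen bundle for ``config`` (see module docs)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # fixed spawning order: truth, one stream per MS screen, per PTM screen,
    # rnai, categories
    streams = root.spawn(4 + len(MS_SCREEN_CONDITIONS) + len(PTM_SCREENS))
    rng_truth = np.random.default_rng(streams[0])
    rng_rnai = np.random.default_rng(streams[1])
    rng_cats = np.random.default_rng(streams[2])
    screen_streams = streams[4:]

    proteins = _protein_ids(config)
    arr = np.array(proteins)
    true_idx = np.sort(rng_truth.choice(config.n_proteins, size=config.n_true_factors,
                                        replace=False))
    true_factors = set(arr[true_idx])
    responders: dict[str, set[str]] = {}
    for sid in (*MS_SCREEN_CONDITIONS, *PTM_SCREENS, "rnai"):
        mask = rng_truth.random(len(true_idx)) < config.sensitivity[sid]
        responders[sid] = set(arr[true_idx[mask]])
    n_gold = int(round(config.gold_fraction * config.n_true_factors))
    gold = set(rng_truth.choice(sorted(true_factors), size=n_gold, replace=False)) \
        if n_gold else set()

    screens: dict[str, list[ScreenTable]] = {}
    ptm: dict[str, PTMSiteTable] = {}
    for stream, sid in zip(screen_streams, (*MS_SCREEN_CONDITIONS, *PTM_SCREENS)):
        rng = np.random.default_rng(stream)
        resp = responders[sid]
        resp_mask = np.isin(arr, sorted(resp))
        covered = (rng.random(config.n_proteins) < (
            config.ms_coverage if sid in MS_SCREEN_CONDITIONS else config.ptm_coverage
        )) | resp_mask  # responders are always detected in their screen
        if sid in MS_SCREEN_CONDITIONS:
            tables = []
            for cond in MS_SCREEN_CONDITIONS[sid]:
                ratios = rng.normal(0.0, config.noise_sd, size=config.n_proteins)
                shift = rng.normal(config.effect_size, config.noise_sd / 2,
                                   size=config.n_proteins)
                ratios = np.where(resp_mask, ratios + shift, ratios)
                ibaq = 10 ** rng.normal(6.0, 1.0, size=config.n_proteins)
                df = pd.DataFrame(
                    {"protein_id": arr[covered],
                     "log2_ratio": ratios[covered],
                     "ibaq": ibaq[covered]}
                ).reset_index(drop=True)
                tables.append(ScreenTable(screen_id=sid, condition=cond, data=df))
            screens[sid] = tables
        else:
            ptm[_MOD_OF[sid]] = _generate_ptm_table(rng, arr[covered],
                                                    np.isin(arr[covered], sorted(resp)),
                                                    _MOD_OF[sid], config)

    rnai_wells = _generate_rnai_wells(rng_rnai, proteins, responders["rnai"], config)
    categories = _generate_categories(rng_cats, proteins, true_factors, gold, config)
    truth = GroundTruth(true_factors=true_factors, responders=responders, gold=gold)
    return Bundle(screens=screens, ptm=ptm, rnai_wells=rnai_wells,
                  categories=categories, truth=truth, config=config)


_MOD_OF = {"ubiquitylome": "ubiquitin", "phosphoproteome": "phospho"}
_SCREEN_OF_MOD = {v: k for k, v in _MOD_OF.items()}


def _generate_ptm_table(rng: np.random.Generator, covered: np.ndarray,
                        responding: np.ndarray, modification: str,
                        config: SimulationConfig) -> PTMSiteTable:
    n_sites = rng.integers(config.sites_min, config.sites_max + 1, size=len(covered))
    pids = np.repeat(covered, n_sites)
    resp_rows = np.repeat(responding, n_sites)
    total = int(n_sites.sum())
    # unique 1-based positions within each protein, drawn from the first
    # 2,000 residues (typical protein lengths)
    if total:
        # k distinct offsets per protein via rejection-free trick: sample k
        # strictly increasing gaps
        gaps = rng.integers(1, 400, size=(len(covered), config.sites_max))
        cum = np.cumsum(gaps, axis=1)
        positions = np.concatenate([cum[i, :k] for i, k in enumerate(n_sites)])
    else:
        positions = np.array([], dtype=int)
    ratios = rng.normal(0.0, config.noise_sd, size=total)
    # one responding site per responding protein: the first of its sites
    first_of_protein = np.r_[True, pids[1:] != pids[:-1]] if total else np.array([], bool)
    shifted = first_of_protein & resp_rows
    ratios[shifted] += rng.normal(config.effect_size, config.noise_sd / 2,
                                  size=int(shifted.sum()))
    if modification == "phospho":
        centers = rng.choice(np.array(list("STY")), size=total,
                             p=list(config.phospho_residue_probs))
        st = np.isin(centers, list("ST"))
        p_q = config.stq_rate / max(np.sum(config.phospho_residue_probs[:2]), 1e-12)
        stq = st & (rng.random(total) < p_q)
        windows = _windows(rng, centers, config.window_flank, stq)
    else:
        centers = np.full(total, "K")
        windows = _windows(rng, centers, config.window_flank, None)
        # a K centre must not be followed by our S/TQ marker logic; windows are free
    df = pd.DataFrame(
        {"protein_id": pids, "residue": centers, "position": positions,
         "window": windows, "log2_ratio": ratios}
    )
    return PTMSiteTable(modification=modification, data=df.reset_index(drop=True))


def _generate_rnai_wells(rng: np.random.Generator, proteins: list[str],
                         low_genes: set[str], config: SimulationConfig) -> list[RNAiWellProfile]:
    rc = config.rnai

    def draw_cells(low_fraction: float) -> np.ndarray:
        n_low = rng.binomial(rc.cells_per_well, low_fraction)
        lows = np.exp(rng.normal(rc.log_low_mean, rc.log_sd, size=n_low))
        highs = np.exp(rng.normal(rc.log_high_mean, rc.log_sd,
                                  size=rc.cells_per_well - n_low))
        return np.concatenate([lows, highs])

    wells: list[RNAiWellProfile] = []
    genes = list(proteins)
    n_plates = int(np.ceil(len(genes) / rc.test_wells_per_plate))
    for p in range(n_plates):
        plate_id = f"PL{p + 1:03d}"
        chunk = genes[p * rc.test_wells_per_plate:(p + 1) * rc.test_wells_per_plate]
        w = 0
        for ctype, count in (("non_targeting", rc.non_targeting_per_plate),
                             ("risc_free", rc.risc_free_per_plate),
                             ("positive_control", rc.positive_controls_per_plate)):
            for _ in range(count):
                w += 1
                frac = rc.knockdown_low_fraction if ctype == "positive_control" \
                    else rc.baseline_low_fraction
                wells.append(RNAiWellProfile(
                    plate_id=plate_id, well_id=f"W{w:03d}",
                    target_gene="CSB_POS" if ctype == "positive_control" else "NONE",
                    uv_treated=True, control_type=ctype, cells=draw_cells(frac)))
        for gene in chunk:
            w += 1
            frac = rc.knockdown_low_fraction if gene in low_genes else rc.baseline_low_fraction
            wells.append(RNAiWellProfile(
                plate_id=plate_id, well_id=f"W{w:03d}", target_gene=gene,
                uv_treated=True, control_type="", cells=draw_cells(frac)))
    return wells


def _generate_categories(rng: np.random.Generator, proteins: list[str],
                         true_factors: set[str], gold: set[str],
                         config: SimulationConfig) -> CategorySet:
    cats: dict[str, tuple[str, set[str]]] = {}
    if gold:
        cats["TCR"] = ("transcription-repair coupling factors (training category)", set(gold))
    if true_factors:
        n_resp = min(20, len(true_factors))
        members = set(rng.choice(sorted(true_factors), size=n_resp, replace=False))
        members |= set(rng.choice(proteins, size=10, replace=False))
        cats["RESPONSE_PATHWAY"] = ("planted damage-response pathway", members)
    for i in range(config.n_random_categories):
        size = int(rng.integers(10, 51))
        cats[f"RAND{i + 1:03d}"] = (
            f"random category {i + 1}",
            set(rng.choice(proteins, size=size, replace=False)),
        )
    return CategorySet(categories=cats, universe=set(proteins))


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-condition defaults with a given seed (and field overrides).

    ``rnai`` may be given as an :class:`RNAiSimConfig` or a plain mapping of
    its fields (as when loaded from YAML); ``spike_in_names`` may be any
    sequence.
    """
    if isinstance(overrides.get("rnai"), Mapping):
        overrides["rnai"] = RNAiSimConfig(**overrides["rnai"])
    if "spike_in_names" in overrides:
        overrides["spike_in_names"] = tuple(overrides["spike_in_names"])
    if "sensitivity" in overrides:
        overrides["sensitivity"] = {**DEFAULT_SENSITIVITY, **overrides["sensitivity"]}
    cfg = SimulationConfig(seed=seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def truth_recovery_report(bundle: Bundle, result: "PipelineResult") -> dict:
    """Compare pipeline output against the planted ground truth.

    Returns per-screen recall/precision of the planted responders, the gold
    training-category medians under the unweighted (aggregate, scaled to
    [0,1]) and weighted schemes, and the median rank of true factors under
    each scheme.  Mirrors the full study's observation that training-category
    weighting raises the gold median.
    """
    from .pipeline import PipelineResult  # noqa: F401  (typing only)

    truth = bundle.truth
    per_screen = {}
    for sid, calls in result.screen_calls.items():
        hits = set(calls.loc[calls["is_hit"], "protein_id"])
        resp = truth.responders.get(sid, set())
        quantified_resp = resp & set(calls["protein_id"])
        recall = len(hits & quantified_resp) / len(quantified_resp) if quantified_resp else np.nan
        precision = len(hits & truth.true_factors) / len(hits) if hits else np.nan
        per_screen[sid] = {"recall": recall, "precision": precision,
                           "n_hits": len(hits), "n_responders": len(resp)}

    master = result.master.set_index("protein_id")
    n_screens = len(result.screen_calls)
    unweighted = (master["aggregate_z"] / n_screens).to_dict()
    weighted = master["weighted_score"].to_dict()
    from .integration import benchmark_median

    gold = sorted(truth.gold)
    report = {
        "per_screen": per_screen,
        "gold_median_unweighted": benchmark_median(unweighted, gold) if gold else np.nan,
        "gold_median_weighted": benchmark_median(weighted, gold) if gold else np.nan,
        "true_factor_median_rank": {},
    }
    for scheme in ("count_score", "aggregate_z", "weighted_score"):
        ranks = master.loc[master.index.isin(truth.true_factors), f"rank_{scheme}"]
        report["true_factor_median_rank"][scheme] = float(ranks.median()) if len(ranks) else np.nan
    return report
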