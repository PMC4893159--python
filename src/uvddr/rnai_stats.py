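"""Low/high-transcriber statistics for the genome-wide RNAi screen.

After UV irradiation a distinct population of lowly transcribing cells
appears in the per-cell nascent-transcription (EU incorporation) readout.
The screen statistic formalizes that observation: a per-plate intensity
boundary is set at a percentile of the pooled UV-treated negative-control
cells, every well's ``fraction_low`` is the share of its cells below the
boundary, and wells are standardized against the same plate's negative
controls with a robust Z.  Knockdowns enriching the low population get large
positive ``z_low`` ("low transcribers"); knockdowns shifting the whole
population up get large positive ``z_median`` ("high transcribers").

The low call takes precedence when both trigger: the low-transcriber
phenotype is the screen's primary axis and its positive controls (CSB,
RNAPII subunits) are low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hit_calling import MAD_SCALE
from .screen_io import RNAiWellProfile

logger = logging.getLogger(__name__)

DEFAULT_LOW_QUANTILE = 25.0
DEFAULT_MIN_CELLS = 50
DEFAULT_Z_THRESHOLD = 2.0


class PlateRejectedError(ValueError):
    """Negative controls carry no usable variance on this plate."""


def low_boundary(control_wells: Sequence[RNAiWellProfile], q: float = DEFAULT_LOW_QUANTILE) -> float:
    """Low-transcription intensity boundary for one plate.

    The ``q``-th percentile (linear interpolation) of the pooled per-cell
    intensities of the plate's UV-treated negative-control wells.  Requires
    at least four such wells with per-cell data.
    """
    ctrls = [w for w in control_wells if w.is_negative_control and w.uv_treated]
    if any(w.cells is None for w in ctrls):
        raise ValueError(
            "negative-control wells lack per-cell intensities; "
            "supply precomputed fraction_low summaries instead"
        )
    if len(ctrls) < 4:
        raise ValueError(f"need >= 4 UV-treated negative-control wells, got {len(ctrls)}")
    pooled = np.concatenate([w.cells for w in ctrls])
    return float(np.percentile(pooled, q))


@dataclass
class WellStatistic:
    plate_id: str
    well_id: str
    target_gene: str
    control_type: str
    n_cells: int
    fraction_low: float
    median_intensity: float
    excluded: bool = False
    z_low: float = np.nan
    z_median: float = np.nan
    call: str = "none"


def well_statistic(
    well: RNAiWellProfile,
    boundary: float,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> WellStatistic:
    """fraction_low and median for one well; wells with too few cells are
    flagged ``excluded`` (lethality/toxicity guard) and never scored."""
    if well.cells is not None:
        n = len(well.cells)
        frac = float(np.mean(well.cells < boundary)) if n else 0.0
        med = float(np.median(well.cells)) if n else np.nan
    else:
        if well.fraction_low is None or well.n_cells is None:
            raise ValueError(f"well {well.well_id} has neither cells nor summary")
        n, frac = well.n_cells, well.fraction_low
        med = np.nan if well.median_intensity is None else well.median_intensity
    return WellStatistic(
        plate_id=well.plate_id,
        well_id=well.well_id,
        target_gene=well.target_gene,
        control_type=well.control_type,
        n_cells=n,
        fraction_low=frac,
        median_intensity=med,
        excluded=n < min_cells,
    )


def _robust_params(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    scale = MAD_SCALE * float(np.median(np.abs(x - med)))
    if scale == 0.0:
        scale = float(np.std(x, ddof=1))
    return med, scale


def plate_normalize(stats: Sequence[WellStatistic]) -> list[WellStatistic]:
    """Standardize one plate's wells against its scored negative controls.

    ``z_low`` is the robust Z of ``fraction_low`` and ``z_median`` of
    ``median_intensity``, both relative to the same plate's negative-control
    wells (median/MAD, SD fallback); low transcription therefore yields
    positive ``z_low`` and negative ``z_median``.  Raises
    :class:`PlateRejectedError` when the controls are entirely degenerate.
    """
    scored = [s for s in stats if not s.excluded]
    ctrls = [s for s in scored if s.control_type in ("non_targeting", "risc_free")]
    if len(ctrls) < 4:
        raise PlateRejectedError(f"plate has {len(ctrls)} scored negative controls (need >= 4)")
    f = np.array([c.fraction_low for c in ctrls])
    m = np.array([c.median_intensity for c in ctrls])
    f_med, f_scale = _robust_params(f)
    m_med, m_scale = _robust_params(m)
    if f_scale == 0.0 and m_scale == 0.0:
        raise PlateRejectedError("negative controls have zero spread in both statistics")
    out = []
    for s in stats:
        s = WellStatistic(**vars(s))
        if not s.excluded:
            s.z_low = (s.fraction_low - f_med) / f_scale if f_scale else np.nan
            s.z_median = (s.median_intensity - m_med) / m_scale if m_scale else np.nan
        out.append(s)
    return out


def _call(z_low: float, z_median: float, threshold: float) -> str:
    if np.isfinite(z_low) and z_low >= threshold:
        return "low"
    if np.isfinite(z_median) and z_median >= threshold:
        return "high"
    return "none"


def call_transcribers(
    stats: Sequence[WellStatistic],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> list[WellStatistic]:
    """Per-well low/high/none calls (low wins when both tails trigger)."""
    out = []
    for s in stats:
        s = WellStatistic(**vars(s))
        if not s.excluded:
            s.call = _call(s.z_low, s.z_median, z_threshold)
        out.append(s)
    return out


def score_wells(
    wells: Sequence[RNAiWellProfile],
    *,
    low_quantile: float = DEFAULT_LOW_QUANTILE,
    min_cells: int = DEFAULT_MIN_CELLS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> list[WellStatistic]:
    """Boundary -> well statistics -> plate normalization -> calls, per plate.

    Plates whose negative controls are degenerate are dropped with a warning.
    """
    by_plate: dict[str, list[RNAiWellProfile]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)
    out: list[WellStatistic] = []
    for plate_id in sorted(by_plate):
        plate = by_plate[plate_id]
        boundary = low_boundary([w for w in plate if w.is_negative_control], q=low_quantile)
        stats = [well_statistic(w, boundary, min_cells=min_cells) for w in plate]
        try:
            stats = plate_normalize(stats)
        except PlateRejectedError as exc:
            logger.warning("plate %s rejected: %s", plate_id, exc)
            continue
        out.extend(call_transcribers(stats, z_threshold=z_threshold))
    return out


def gene_level_calls(
    stats: Sequence[WellStatistic],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Aggregate test wells to gene level.

    A gene's z statistics are the medians over its scored wells.  The call is
    the low/high rule applied to those medians; with replicates (>= 2 wells)
    at least two wells must individually agree with the gene-level call,
    otherwise the call drops to ``none``.  Control wells are excluded.

    Returns a DataFrame with columns ``gene``, ``z_low``, ``z_median``,
    ``call``, ``n_wells``, sorted by gene.
    """
    rows = []
    test = [s for s in stats if not s.control_type and not s.excluded]
    by_gene: dict[str, list[WellStatistic]] = {}
    for s in test:
        by_gene.setdefault(s.target_gene, []).append(s)
    for gene in sorted(by_gene):
        g = by_gene[gene]
        z_low = float(np.median([s.z_low for s in g]))
        z_median = float(np.median([s.z_median for s in g]))
        call = _call(z_low, z_median, z_threshold)
        if len(g) >= 2 and call != "none":
            concordant = sum(1 for s in g if s.call == call)
            if concordant < 2:
                call = "none"
        rows.append({"gene": gene, "z_low": z_low, "z_median": z_median,
                     "call": call, "n_wells": len(g)})
    return pd.DataFrame(rows, columns=["gene", "z_low", "z_median", "call", "n_wells"])


def as_screen_calls(gene_table: pd.DataFrame, z_threshold: float = DEFAULT_Z_THRESHOLD) -> pd.DataFrame:
    """Convert the gene-level table into the consolidated hit-call layout
    used by integration (the RNAi screen's response tail is the
    low-transcriber axis, so ``z`` is ``z_low``)."""
    return pd.DataFrame(
        {
            "protein_id": gene_table["gene"],
            "screen_id": "rnai",
            "z": gene_table["z_low"],
            "direction": np.where(gene_table["z_low"] >= 0, 1, -1),
            "is_hit": (gene_table["call"] == "low").to_numpy(),
        }
    ).sort_values("protein_id", kind="stable").reset_index(drop=True)
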