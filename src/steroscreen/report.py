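"""Summary statistics and the risk-compound report table.

The headline quantities of the screening study: counts per categorical flag
(soil mobility, bioaccumulation, blood-brain barrier penetration, P-gp
liability among BBB+ compounds, placental non-crossers, the combined
pregnancy-risk set) and two squared Pearson correlations — between the GST
and NAT2 docking affinities (near zero: the two binding sites respond to
different ligand properties) and between the unbound brain/plasma ratio and
the total brain/blood ratio (high: the two BBB metrics broadly agree).

Correlations are computed on the table values as printed (two decimals),
since the published figures derive from the same tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (ClassificationProfile, DEFAULT_THRESHOLDS, Thresholds,
                       pregnancy_risk_filter)
from .io import CompoundRecord

__all__ = ["SummaryStats", "squared_correlation", "summarize", "render_table5",
           "table5_markdown"]


@dataclass
class SummaryStats:
    n_compounds: int
    n_hm_im: int
    n_bbb_pos: int
    pct_bbb_pos: float
    n_pgp_among_bbb: int
    n_bioacc: int
    n_placenta_noncross: int
    r2_gst_nat2: float | None
    r2_kpuubr_logbb: float | None
    n_risk: int


def squared_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson correlation, on pairwise-complete observations.

    Requires at least 3 complete pairs and nonzero variance in both
    vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def summarize(
    profiles: Sequence[ClassificationProfile],
    table1: Sequence[CompoundRecord],
    table3: Sequence[CompoundRecord] | None = None,
) -> SummaryStats:
    """Headline counts and correlations for a screened compound set."""
    n = len(profiles)
    by_id = {r.compound_id: r for r in table1}
    n_hm_im = sum(1 for p in profiles
                  if p.mobility is not None and p.mobility.paired_label == "HM/IM")
    bbb_pos = [p for p in profiles if p.bbb_positive]
    n_pgp = sum(1 for p in bbb_pos if p.pgp_substrate)
    n_bioacc = sum(1 for p in profiles if p.bioaccumulative)
    n_noncross = sum(1 for p in profiles if p.placenta_crossing is False)

    r2_gst_nat2 = None
    if table3:
        gst = [r.k_gst for r in table3]
        nat2 = [r.k_nat2 for r in table3]
        if all(v is not None for v in gst + nat2):
            r2_gst_nat2 = squared_correlation(gst, nat2)

    pairs = [(by_id[p.compound_id].log_kpuubr, by_id[p.compound_id].log_bb)
             for p in profiles if p.compound_id in by_id]
    r2_kp_bb = None
    if pairs and all(a is not None and b is not None for a, b in pairs):
        r2_kp_bb = squared_correlation([a for a, _ in pairs], [b for _, b in pairs])

    try:
        n_risk = len(pregnancy_risk_filter(profiles))
    except ValueError:
        n_risk = sum(1 for p in profiles if p.pregnancy_risk)

    return SummaryStats(
        n_compounds=n,
        n_hm_im=n_hm_im,
        n_bbb_pos=len(bbb_pos),
        pct_bbb_pos=100.0 * len(bbb_pos) / n if n else math.nan,
        n_pgp_among_bbb=n_pgp,
        n_bioacc=n_bioacc,
        n_placenta_noncross=n_noncross,
        r2_gst_nat2=r2_gst_nat2,
        r2_kpuubr_logbb=r2_kp_bb,
        n_risk=n_risk,
    )


def _coarse_mobility(log_koc: float, thresholds: Thresholds) -> str:
    """The summary table's own coarse soil-mobility scheme: 'Low' mobility
    above log Koc 4, 'Medium' between 2 and 4, 'High' below 2."""
    if log_koc > thresholds.coarse_mobility_low:
        return "Low"
    if log_koc >= thresholds.coarse_mobility_medium:
        return "Medium"
    return "High"


def render_table5(
    profiles: Sequence[ClassificationProfile],
    table1: Sequence[CompoundRecord],
    table3: Sequence[CompoundRecord] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """One row per pregnancy-risk compound, with the summary-style
    categorical columns.

    Note the bioaccumulation column uses the summary table's own cut-off
    (log BCF >= 3 -> 'High'), which is deliberately separate from the
    stricter screening flag.
    """
    by_id = {r.compound_id: r for r in table1}
    risk_ids = pregnancy_risk_filter(profiles)
    rows = []
    for cid in risk_ids:
        rec = by_id[cid]
        rows.append({
            "compound_id": cid,
            "name": rec.name,
            "soil_mobility": _coarse_mobility(rec.log_koc, thresholds)
            if rec.log_koc is not None else None,
            "bioaccumulation": ("High" if rec.log_bcf >= 3.0 else "Low")
            if rec.log_bcf is not None else None,
            "gi_absorption": ("High" if rec.hia_pct >= thresholds.hia_cutoff else "Low")
            if rec.hia_pct is not None else None,
            "skin_permeability": "Yes",
            "placenta_permeability": "Yes",
            "cns_availability": "Yes",
            "gst_affinity": "High",
            "nat2_affinity": "High",
        })
    columns = ["compound_id", "name", "soil_mobility", "bioaccumulation",
               "gi_absorption", "skin_permeability", "placenta_permeability",
               "cns_availability", "gst_affinity", "nat2_affinity"]
    return pd.DataFrame(rows, columns=columns)


def table5_markdown(frame: pd.DataFrame) -> str:
    """Markdown rendering of the risk-compound table."""
    if frame.empty:
        return "(no pregnancy-risk compounds)\n"
    return frame.to_markdown(index=False) + "\n"
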