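"""Threshold rules turning numeric properties into categorical flags.

All cut-offs are held in a single :class:`Thresholds` record whose defaults
are the published ones, so every rule is auditable and overridable in one
place:

* soil mobility — the EPA six-class log K_oc scheme (<1 very mobile, 1-2
  mobile, ... >5 immobile), with lower-inclusive interval closure (the
  source states ranges without closure and no tabulated value sits on a
  boundary);
* bioaccumulation — nominally BCF >= 2000, i.e. log BCF >= 3.301; the
  default threshold is 3.28 because the source's own flagging marks 3.28
  and 3.29 as bioaccumulative (rounding of unrounded upstream estimates);
* blood-brain barrier — unbound brain/plasma ratio above 0.3, i.e.
  log K_p,uu,br > log10(0.3), strict;
* placental transfer — log FM >= -0.52, inclusive (a compound printed at
  exactly -0.52 is counted as crossing);
* intestinal absorption — HIA >= 30% counts as absorbed;
* enzyme affinity — docking score strictly more negative than the
  reference ligand's (glutathione for GST, coenzyme A for NAT2).

A compound is flagged as a pregnancy risk when it crosses both the
blood-brain barrier and the placenta and binds both placental
detoxification enzymes more strongly than their natural substrates.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from .io import CompoundRecord, ReferenceLigands

__all__ = [
    "MobilityClass",
    "Thresholds",
    "ClassificationProfile",
    "classify_mobility",
    "classify_bioaccumulation",
    "classify_bbb",
    "classify_placenta",
    "classify_hia",
    "classify_enzyme_affinity",
    "build_profiles",
    "pregnancy_risk_filter",
    "profiles_frame",
    "export_profiles",
]

BBB_CUTOFF_LOG = math.log10(0.3)


class MobilityClass(enum.Enum):
    """EPA soil-mobility class, with the coarse paired label used in the
    summary tables (VM/M, MM/SM, HM/IM)."""

    VERY_MOBILE = ("very_mobile", "VM/M")
    MOBILE = ("mobile", "VM/M")
    MODERATELY_MOBILE = ("moderately_mobile", "MM/SM")
    SLIGHTLY_MOBILE = ("slightly_mobile", "MM/SM")
    HARDLY_MOBILE = ("hardly_mobile", "HM/IM")
    IMMOBILE = ("immobile", "HM/IM")

    @property
    def label(self) -> str:
        return self.value[0]

    @property
    def paired_label(self) -> str:
        return self.value[1]


_MOBILITY_ORDER = list(MobilityClass)


@dataclass(frozen=True)
class Thresholds:
    """All classification cut-offs; defaults reproduce the published rules."""

    bcf_cutoff: float = 3.28           # log BCF; nominal log10(2000)=3.301, see module docstring
    bbb_cutoff: float = BBB_CUTOFF_LOG  # log K_p,uu,br, strict >
    fm_cutoff: float = -0.52           # log FM, inclusive >=
    hia_cutoff: float = 30.0           # percent, inclusive >=
    coarse_mobility_low: float = 4.0   # summary-table scheme: log Koc > 4 -> "Low"
    coarse_mobility_medium: float = 2.0  # 2..4 -> "Medium", < 2 -> "High"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


DEFAULT_THRESHOLDS = Thresholds()


def classify_mobility(log_koc: float) -> MobilityClass:
    """Six-way EPA mobility class; intervals are lower-inclusive
    ([1,2) mobile, [2,3) moderately mobile, ...)."""
    if not math.isfinite(log_koc):
        raise ValueError(f"log_koc must be finite, got {log_koc}")
    index = min(max(int(math.floor(log_koc)), 0), 5)
    return _MOBILITY_ORDER[index]


def classify_bioaccumulation(log_bcf: float, threshold: float = DEFAULT_THRESHOLDS.bcf_cutoff) -> bool:
    """True when the compound is expected to bioaccumulate (log BCF at or
    above the threshold)."""
    if not math.isfinite(log_bcf):
        raise ValueError(f"log_bcf must be finite, got {log_bcf}")
    return log_bcf >= threshold


def classify_bbb(log_kpuubr: float, cutoff: float = BBB_CUTOFF_LOG) -> bool:
    """True (BBB+) when the unbound brain/plasma ratio exceeds 0.3
    (strict inequality on the log scale)."""
    if not math.isfinite(log_kpuubr):
        raise ValueError(f"log_kpuubr must be finite, got {log_kpuubr}")
    return log_kpuubr > cutoff


def classify_placenta(log_fm: float, cutoff: float = DEFAULT_THRESHOLDS.fm_cutoff) -> bool:
    """True when the compound crosses the placenta easily (log FM at or
    above the cut-off; inclusive at the boundary)."""
    if not math.isfinite(log_fm):
        raise ValueError(f"log_fm must be finite, got {log_fm}")
    return log_fm >= cutoff


def classify_hia(hia_pct: float, cutoff: float = DEFAULT_THRESHOLDS.hia_cutoff) -> bool:
    """True when the compound is absorbed from the GI tract (HIA >= 30%)."""
    if not 0.0 <= hia_pct <= 100.0:
        raise ValueError(f"hia_pct must be in [0, 100], got {hia_pct}")
    return hia_pct >= cutoff


def classify_enzyme_affinity(k: float, k_ref: float) -> bool:
    """True when the docking affinity is strictly more negative than the
    reference ligand's."""
    if not (math.isfinite(k) and math.isfinite(k_ref)):
        raise ValueError("affinities must be finite")
    return k < k_ref


@dataclass
class ClassificationProfile:
    """Per-compound categorical flags.  ``None`` marks a flag that could not
    be computed because its input was missing."""

    compound_id: str
    mobility: MobilityClass | None = None
    bioaccumulative: bool | None = None
    bbb_positive: bool | None = None
    placenta_crossing: bool | None = None
    hia_absorbed: bool | None = None
    pgp_substrate: bool | None = None
    gst_high_affinity: bool | None = None
    nat2_high_affinity: bool | None = None

    @property
    def pregnancy_risk(self) -> bool | None:
        flags = (self.bbb_positive, self.placenta_crossing,
                 self.gst_high_affinity, self.nat2_high_affinity)
        if any(f is None for f in flags):
            return None
        return all(flags)


def build_profiles(
    table1: Sequence[CompoundRecord],
    table3: Sequence[CompoundRecord] | None = None,
    reference: ReferenceLigands | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[ClassificationProfile]:
    """Apply every classifier to a property table (plus, optionally, an
    affinity table with its reference ligands), in input order."""
    affinities = {r.compound_id: r for r in table3} if table3 else {}
    profiles = []
    for rec in table1:
        prof = ClassificationProfile(compound_id=rec.compound_id,
                                     pgp_substrate=rec.pgp_substrate)
        if rec.log_koc is not None:
            prof.mobility = classify_mobility(rec.log_koc)
        if rec.log_bcf is not None:
            prof.bioaccumulative = classify_bioaccumulation(rec.log_bcf, thresholds.bcf_cutoff)
        if rec.log_kpuubr is not None:
            prof.bbb_positive = classify_bbb(rec.log_kpuubr, thresholds.bbb_cutoff)
        if rec.log_fm is not None:
            prof.placenta_crossing = classify_placenta(rec.log_fm, thresholds.fm_cutoff)
        if rec.hia_pct is not None:
            prof.hia_absorbed = classify_hia(rec.hia_pct, thresholds.hia_cutoff)
        aff = affinities.get(rec.compound_id)
        if aff is not None and reference is not None:
            if aff.k_gst is not None:
                prof.gst_high_affinity = classify_enzyme_affinity(aff.k_gst, reference.k_gst_ref)
            if aff.k_nat2 is not None:
                prof.nat2_high_affinity = classify_enzyme_affinity(aff.k_nat2, reference.k_nat2_ref)
        profiles.append(prof)
    return profiles


def pregnancy_risk_filter(profiles: Iterable[ClassificationProfile]) -> list[str]:
    """Compounds flagged on all four risk axes (BBB+, placenta-crossing,
    GST and NAT2 affinity above reference), in input order.

    A profile with any of the four flags missing is an error naming the
    compound and the flag.
    """
    risky = []
    for prof in profiles:
        for flag in ("bbb_positive", "placenta_crossing",
                     "gst_high_affinity", "nat2_high_affinity"):
            if getattr(prof, flag) is None:
                raise ValueError(f"{prof.compound_id}: flag {flag!r} not computed")
        if prof.pregnancy_risk:
            risky.append(prof.compound_id)
    return risky


def profiles_frame(profiles: Sequence[ClassificationProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame mirroring the property table's categorical
    columns plus the combined risk flag."""
    rows = []
    for p in profiles:
        rows.append({
            "compound_id": p.compound_id,
            "mobility": None if p.mobility is None else p.mobility.label,
            "mobility_pair": None if p.mobility is None else p.mobility.paired_label,
            "bioaccumulative": p.bioaccumulative,
            "bbb": None if p.bbb_positive is None else ("BBB+" if p.bbb_positive else "BBB-"),
            "placenta_crossing": p.placenta_crossing,
            "hia_absorbed": p.hia_absorbed,
            "pgp_substrate": p.pgp_substrate,
            "gst_high_affinity": p.gst_high_affinity,
            "nat2_high_affinity": p.nat2_high_affinity,
            "pregnancy_risk": p.pregnancy_risk,
        })
    return pd.DataFrame(rows)


def export_profiles(profiles: Sequence[ClassificationProfile], csv_path,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS) -> None:
    """Write the profile CSV plus a JSON sidecar echoing the thresholds used
    (provenance for audits)."""
    frame = profiles_frame(profiles)
    frame.to_csv(csv_path, index=False)
    sidecar = str(csv_path) + ".thresholds.json"
    with open(sidecar, "w") as fh:
        fh.write(thresholds.to_json())
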