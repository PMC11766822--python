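"""Compound and property table I/O.

The package ships three bundled fixtures:

``table1``
    Environmental-fate and pharmacokinetic properties of 37 steroid drugs
    (soil/water log K_oc, log BCF, log BB, log PS, log K_p,uu,br, P-gp
    substrate flag, HIA%, skin log K_p, placental log FM, rule-of-five
    violation count), transcribed digit-for-digit from the published table,
    together with the published categorical labels (soil-mobility pair,
    BBB+/-, bioaccumulation and placenta bold marks) so that classifier
    output can be checked cell by cell.
``table3``
    Docking affinities (kcal/mol) of the same 37 compounds for the placental
    enzymes GST and NAT2, plus the reference-ligand affinities (glutathione
    for GST, coenzyme A for NAT2).
``registry``
    Curated SMILES for the 37 named steroids.  Stereochemistry is omitted on
    purpose: every descriptor consumed downstream is 2D/topological, and the
    flat structures were validated against the known molecular formulae.

External tables use a plain CSV dialect: comma-separated, UTF-8, header row,
empty cell = missing value.  Typographic minus signs (U+2212) are normalised
to ASCII hyphens at read time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dataclass_fields
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

log = logging.getLogger(__name__)

_MINUS = "−"

#: numeric CompoundRecord fields, in canonical column order
NUMERIC_FIELDS = (
    "log_koc",
    "log_bcf",
    "log_bb",
    "log_ps",
    "log_kpuubr",
    "hia_pct",
    "log_kp_skin",
    "log_fm",
    "k_gst",
    "k_nat2",
)


@dataclass
class CompoundRecord:
    """One compound: identity, optional structure, and externally predicted
    property columns.  ``None`` marks an explicitly missing value — numeric
    fields are never silently zero-filled."""

    compound_id: str
    name: str = ""
    smiles: str | None = None
    log_koc: float | None = None
    log_bcf: float | None = None
    log_bb: float | None = None
    log_ps: float | None = None
    log_kpuubr: float | None = None
    pgp_substrate: bool | None = None
    hia_pct: float | None = None
    log_kp_skin: float | None = None
    log_fm: float | None = None
    lipinski_violations: int | None = None
    k_gst: float | None = None
    k_nat2: float | None = None

    def __post_init__(self) -> None:
        if self.hia_pct is not None and not 0.0 <= self.hia_pct <= 100.0:
            raise ValueError(
                f"{self.compound_id}: hia_pct={self.hia_pct} outside [0, 100]"
            )


class ReferenceLigands(NamedTuple):
    """Docking affinities (kcal/mol) of the natural substrates used as the
    enzyme-affinity yardsticks: glutathione (GST) and coenzyme A (NAT2)."""

    k_gst_ref: float
    k_nat2_ref: float


class Table3(NamedTuple):
    records: list[CompoundRecord]
    reference: ReferenceLigands


def _parse_float(value, row_label: str, column: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).replace(_MINUS, "-").strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        log.warning("unparseable numeric cell at row %r, column %r: %r",
                    row_label, column, value)
        return None


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip().lower()
    if not text:
        return None
    return text in {"yes", "true", "1", "y"}


def read_compound_table(path, schema: dict[str, str] | None = None) -> list[CompoundRecord]:
    """Read a delimiter-separated compound table into records.

    ``schema`` maps file column names onto :class:`CompoundRecord` field
    names for tables whose headers do not already match.  Unparseable numeric
    cells become explicit missing values with a logged warning; a missing
    ``compound_id`` column or duplicated ids are hard errors.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        frame = frame.rename(columns=schema)
    if "compound_id" not in frame.columns:
        raise ValueError(f"{path}: no 'compound_id' column (have {list(frame.columns)})")
    ids = frame["compound_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate compound ids: {dupes}")

    known = {f.name for f in dataclass_fields(CompoundRecord)}
    records = []
    for _, row in frame.iterrows():
        kwargs: dict = {"compound_id": row["compound_id"]}
        for col in frame.columns:
            if col == "compound_id" or col not in known:
                continue
            raw = row[col]
            if col in ("name", "smiles"):
                kwargs[col] = str(raw) if str(raw).strip() else ("" if col == "name" else None)
            elif col == "pgp_substrate":
                kwargs[col] = _parse_bool(raw)
            elif col == "lipinski_violations":
                v = _parse_float(raw, row["compound_id"], col)
                kwargs[col] = None if v is None else int(v)
            else:
                kwargs[col] = _parse_float(raw, row["compound_id"], col)
        records.append(CompoundRecord(**kwargs))
    return records


def write_compound_table(records: list[CompoundRecord], path) -> None:
    """Write records as CSV (empty cell = missing), round-trippable through
    :func:`read_compound_table`."""
    cols = [f.name for f in dataclass_fields(CompoundRecord)]
    rows = []
    for rec in records:
        row = {}
        for col in cols:
            value = getattr(rec, col)
            if value is None:
                row[col] = ""
            elif col == "pgp_substrate":
                row[col] = "Yes" if value else "No"
            else:
                row[col] = value
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _fixture_path(name: str):
    return resources.files("steroscreen.data").joinpath(f"{name}.csv")


def fixture_frame(name: str) -> pd.DataFrame:
    """Raw fixture as a DataFrame, including the published categorical label
    columns (``mobility``, ``bbb``, ``bioaccumulative``, ``placenta_noncrossing``)
    that are not part of :class:`CompoundRecord`."""
    if name not in {"table1", "table3", "registry"}:
        raise ValueError(f"unknown fixture {name!r}; expected table1, table3 or registry")
    with resources.as_file(_fixture_path(name)) as p:
        return pd.read_csv(p, dtype=str, keep_default_na=False)


def load_fixture(name: str):
    """Load a bundled fixture.

    ``table1``  -> list of 37 :class:`CompoundRecord`
    ``table3``  -> :class:`Table3` (37 records with k_gst/k_nat2, plus the
    reference-ligand affinities)
    ``registry`` -> list of 37 records carrying curated SMILES
    """
    if name == "table1":
        with resources.as_file(_fixture_path("table1")) as p:
            return read_compound_table(p)
    if name == "table3":
        with resources.as_file(_fixture_path("table3")) as p:
            records = read_compound_table(p)
        ref_rows = [r for r in records if r.compound_id == "REF"]
        if len(ref_rows) != 1:
            raise ValueError("table3 fixture must contain exactly one REF row")
        ref = ReferenceLigands(ref_rows[0].k_gst, ref_rows[0].k_nat2)
        if not (ref.k_gst_ref < 0 and ref.k_nat2_ref < 0):
            raise ValueError("reference-ligand affinities must be strictly negative")
        return Table3([r for r in records if r.compound_id != "REF"], ref)
    if name == "registry":
        with resources.as_file(_fixture_path("registry")) as p:
            return read_compound_table(p)
    raise ValueError(f"unknown fixture {name!r}; expected table1, table3 or registry")


def read_structures(path) -> dict[str, Chem.Mol]:
    """Read SMILES (``SMILES [id]`` per line) or SDF into sanitized molecules
    keyed by compound id.

    Per-molecule parse failures are logged and skipped; zero parseable
    structures is a hard error.
    """
    path = Path(path)
    mols: dict[str, Chem.Mol] = {}
    failures: list[str] = []
    RDLogger.DisableLog("rdApp.error")
    try:
        if path.suffix.lower() == ".sdf":
            for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
                if mol is None:
                    failures.append(f"record {i}")
                    continue
                cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
                mols[cid] = mol
        elif path.suffix.lower() == ".csv":
            for rec in read_compound_table(path):
                if not rec.smiles:
                    continue
                mol = Chem.MolFromSmiles(rec.smiles)
                if mol is None:
                    failures.append(rec.compound_id)
                    continue
                mols[rec.compound_id] = mol
        else:
            for i, line in enumerate(path.read_text().splitlines()):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                cid = parts[1].strip() if len(parts) > 1 else f"mol{i}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    failures.append(cid)
                    continue
                mols[cid] = mol
    finally:
        RDLogger.EnableLog("rdApp.error")
    for cid in failures:
        log.warning("%s: unparseable structure %s skipped", path, cid)
    if not mols:
        raise ValueError(f"{path}: no parseable structures")
    return mols


def registry_structures() -> dict[str, Chem.Mol]:
    """Sanitized molecules for the 37 bundled steroids, keyed by compound id."""
    mols = {}
    for rec in load_fixture("registry"):
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:  # pragma: no cover - fixture is validated by tests
            raise ValueError(f"registry fixture: bad SMILES for {rec.compound_id}")
        mols[rec.compound_id] = mol
    return mols
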