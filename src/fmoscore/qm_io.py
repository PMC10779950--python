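"""Readers and writers for QM engine outputs and energy tables.

Two text dialects are supported:

* A GAMESS-FMO-style PIEDA listing: a ``FRAGMENT LIST`` block (one fragment
  per line, the ligand tagged ``LIGAND``) followed by a pair-interaction
  decomposition table with columns I, J, ES, EX, CT+MIX, DI, TOTAL.  The
  layout is a fixed-width rendering of the FMO 5.1 PIEDA print; parsing is
  whitespace-tolerant so the same reader accepts both aligned and loosely
  spaced variants.  Real GAMESS logs differ across versions and print levels,
  so full fidelity to every release is out of scope; the dialect is the one
  emitted by :func:`fmoscore.synthetic.gen_qm_fixture_texts`.
* A MOPAC-style PM7/COSMO output carrying one ``FINAL HEAT OF FORMATION``
  value; the solvation free energy is the solvated-minus-gas difference.

Energies are taken as kcal/mol unless a unit banner says HARTREE, in which
case they are converted once, here, at the parser boundary (factor 627.509).
The tabular format is the CSV column contract of
:class:`fmoscore.thermo.ComplexEnergyRecord`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, SchemaError
from .pieda import Fragment, PairInteraction, PiedaTable
from .thermo import HARTREE_TO_KCAL, SOLVATION_MODELS, ComplexEnergyRecord, record_from_mapping

__all__ = [
    "SolvationRecord",
    "parse_fmo_output",
    "parse_mopac_cosmo",
    "read_energy_table",
    "write_energy_table",
    "ENERGY_TABLE_COLUMNS",
]

#: Column contract for energy-table CSV files; empty cells mean absent terms.
ENERGY_TABLE_COLUMNS = (
    "complex_id",
    "target_id",
    "e_int",
    *(f"g_sol_{m}" for m in SOLVATION_MODELS),
    "e_def",
    "neg_t_ds",
    "dg_exp",
    "ic50_molar",
)

_MANDATORY_COLUMNS = ("complex_id", "target_id", "e_int")


@dataclass(frozen=True)
class SolvationRecord:
    """Solvation free energy of one species from paired gas/solvated runs (kcal/mol)."""

    species_id: str
    g_solvated: float
    g_gas: float
    delta_g_sol: float

    def __post_init__(self) -> None:
        if abs(self.delta_g_sol - (self.g_solvated - self.g_gas)) > 1e-6:
            raise ValueError("delta_g_sol must equal g_solvated - g_gas")


_NFRAG_RE = re.compile(r"FRAGMENT LIST\s+NFRAG\s*=\s*(\d+)", re.IGNORECASE)
_PIEDA_HEADER_RE = re.compile(r"PAIR INTERACTION ENERGY DECOMPOSITION", re.IGNORECASE)
_UNITS_RE = re.compile(r"\bUNITS?\s*:?\s*(KCAL/MOL|HARTREE)", re.IGNORECASE)
_HOF_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/MOL", re.IGNORECASE
)


def parse_fmo_output(text: str) -> PiedaTable:
    """Parse an FMO output text into a :class:`PiedaTable`.

    Fragment order follows the file; pair indices in the text are 1-based and
    unordered ((I,J) and (J,I) denote the same pair).  Raises
    :class:`ParseError` with line context for a missing section or a
    malformed row.
    """
    lines = text.splitlines()
    scale = 1.0
    for ln in lines:
        m = _UNITS_RE.search(ln)
        if m:
            if m.group(1).upper() == "HARTREE":
                scale = HARTREE_TO_KCAL
            break

    # fragment list
    frag_start = nfrag = None
    for k, ln in enumerate(lines):
        m = _NFRAG_RE.search(ln)
        if m:
            frag_start, nfrag = k + 1, int(m.group(1))
            break
    if frag_start is None:
        raise ParseError("no FRAGMENT LIST section found")
    fragments: list[Fragment] = []
    k = frag_start
    while len(fragments) < nfrag and k < len(lines):
        ln = lines[k]
        k += 1
        if not ln.strip():
            continue
        tokens = ln.split()
        if len(tokens) < 2 or not tokens[0].isdigit():
            raise ParseError("malformed fragment line", line_no=k, line=ln)
        idx = int(tokens[0])
        if idx != len(fragments) + 1:
            raise ParseError(
                f"fragment index {idx} out of order (expected {len(fragments) + 1})",
                line_no=k,
                line=ln,
            )
        is_ligand = tokens[-1].upper() == "LIGAND"
        label = tokens[1] if is_ligand else " ".join(tokens[1:])
        fragments.append(Fragment(label=label, is_ligand=is_ligand))
    if len(fragments) < nfrag:
        raise ParseError(f"fragment list ended after {len(fragments)} of {nfrag} entries")

    # PIEDA table
    pieda_start = None
    for k, ln in enumerate(lines):
        if _PIEDA_HEADER_RE.search(ln) or ln.strip().upper() == "PIEDA":
            pieda_start = k + 1
            break
    if pieda_start is None:
        raise ParseError("no PIEDA section found")
    k = pieda_start
    # skip the column-header line (contains ES and TOTAL) and any dashes
    while k < len(lines):
        up = lines[k].upper()
        if "ES" in up.split() and "TOTAL" in up.split():
            k += 1
            break
        if lines[k].strip() and not set(lines[k].strip()) <= {"-", "="}:
            raise ParseError("PIEDA column header not found", line_no=k + 1, line=lines[k])
        k += 1

    pairs: list[PairInteraction] = []
    while k < len(lines):
        ln = lines[k]
        stripped = ln.strip()
        k += 1
        if not stripped or stripped.upper().startswith("END"):
            break
        if set(stripped) <= {"-", "="}:
            continue
        tokens = stripped.split()
        if len(tokens) != 7:
            raise ParseError(
                f"PIEDA row has {len(tokens)} fields, expected 7 (I J ES EX CT+MIX DI TOTAL)",
                line_no=k,
                line=ln,
            )
        try:
            i, j = int(tokens[0]), int(tokens[1])
            es, ex, ct, di, tot = (float(t) * scale for t in tokens[2:])
        except ValueError:
            raise ParseError("non-numeric PIEDA row", line_no=k, line=ln) from None
        pairs.append(PairInteraction(i=i - 1, j=j - 1, es=es, ex=ex, ct_mix=ct, di=di, total=tot))
    try:
        return PiedaTable(fragments=fragments, pairs=pairs)
    except ValueError as exc:
        raise ParseError(f"inconsistent PIEDA table: {exc}") from exc


def _single_hof(text: str, which: str) -> float:
    matches = _HOF_RE.findall(text)
    if len(matches) != 1:
        raise ParseError(
            f"expected exactly one FINAL HEAT OF FORMATION in the {which} output, "
            f"found {len(matches)}"
        )
    return float(matches[0])


def parse_mopac_cosmo(
    gas_text: str, solvated_text: str, species_id: str = "species"
) -> SolvationRecord:
    """Pair a gas-phase and a COSMO-solvated MOPAC-style output into a solvation record.

    Each text must carry exactly one final heat of formation;
    ``delta_g_sol = solvated - gas`` in kcal/mol.
    """
    g_gas = _single_hof(gas_text, "gas-phase")
    g_solv = _single_hof(solvated_text, "solvated")
    return SolvationRecord(
        species_id=species_id, g_solvated=g_solv, g_gas=g_gas, delta_g_sol=g_solv - g_gas
    )


def read_energy_table(path: str | Path) -> list[ComplexEnergyRecord]:
    """Read a ComplexEnergyRecord CSV; unknown columns are ignored."""
    df = pd.read_csv(path, dtype={"complex_id": str, "target_id": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"energy table {path} lacks mandatory columns: {missing}")
    records = []
    for _, row in df.iterrows():
        d = {k: row[k] for k in df.columns}
        if not math.isfinite(float(row["e_int"])):
            raise SchemaError(f"row {row['complex_id']!r} lacks the mandatory e_int value")
        records.append(record_from_mapping(d))
    return records


def write_energy_table(records: Iterable[ComplexEnergyRecord], path: str | Path) -> None:
    """Write records as CSV per the column contract; absent terms become empty cells."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "complex_id": r.complex_id,
            "target_id": r.target_id,
            "e_int": r.e_int,
            "e_def": r.e_def,
            "neg_t_ds": r.neg_t_ds,
            "dg_exp": r.dg_exp,
            "ic50_molar": r.ic50_molar,
        }
        for m in SOLVATION_MODELS:
            row[f"g_sol_{m}"] = r.g_sol.get(m)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(ENERGY_TABLE_COLUMNS))
    df.to_csv(path, index=False)


def records_to_frame(records: Sequence[ComplexEnergyRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the CSV column layout (absent terms as NaN)."""
    rows = []
    for r in records:
        row = {
            "complex_id": r.complex_id,
            "target_id": r.target_id,
            "e_int": r.e_int,
            **{f"g_sol_{m}": r.g_sol.get(m) for m in SOLVATION_MODELS},
            "e_def": r.e_def,
            "neg_t_ds": r.neg_t_ds,
            "dg_exp": r.dg_exp,
            "ic50_molar": r.ic50_molar,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ENERGY_TABLE_COLUMNS))
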