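"""Compound catalog: LC-HRMS table loading, mass validation, fragment annotation.

The packaged catalog transcribes the negative-ion-mode constituent table of
the five-herb anti-arrhythmic formulation under study: 71 chromatographic
peaks with retention time, detected m/z, molecular formula, printed mass
error (ppm) and MS/MS fragments, plus a herb source code (SQ = Notoginseng,
DS = Codonopsis, HJ = Polygonatum, GS = Nard).

Validation recomputes each row's theoretical adduct m/z from its formula
and compares the signed ppm error against the printed value; rows whose
printed numbers conflict with their own arithmetic are listed in a
"known discrepancies" sidecar rather than silently corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .formula import (
    MolecularFormula,
    adduct_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    round_half_away,
)

__all__ = [
    "CompoundRecord",
    "FragmentAnnotation",
    "LOSS_LIBRARY",
    "load_catalog",
    "load_known_discrepancies",
    "validate_catalog",
    "annotate_fragment",
    "packaged_catalog_path",
]

#: Neutral-loss library (Da). Xyl and Api are isomeric pentoses and share
#: one mass class; annotation therefore reports the class, not the sugar.
LOSS_LIBRARY: dict[str, float] = {
    "Glc": 162.05282,
    "Rha": 146.05791,
    "Xyl/Api": 132.04226,
    "H2O": 18.01056,
    "CO2": 43.98983,
    "CH2O": 30.01057,
    "FA": 46.00548,
}

#: Candidate adducts in selection order.
ADDUCT_ORDER = ("[M-H]-", "[M-H+FA]-")

REQUIRED_COLUMNS = ("peak_no", "tr_min", "name", "detected_mz", "formula",
                    "error_ppm", "fragments", "source")


@dataclass(frozen=True)
class CompoundRecord:
    """One catalog row."""

    peak_no: int
    t_r: float
    name: str
    detected_mz: float
    formula: MolecularFormula | None
    printed_error_ppm: float | None
    fragments: tuple[tuple[float, str], ...] = ()
    source: str | None = None

    @property
    def identified(self) -> bool:
        return self.name != "Unknown"


@dataclass(frozen=True)
class FragmentAnnotation:
    """Result of explaining a fragment m/z as precursor [M-H]- minus losses."""

    fragment_mz: float
    loss_composition: tuple[str, ...]
    theoretical_mz: float
    delta_da: float
    matched: bool


def packaged_catalog_path() -> Path:
    """Path of the catalog CSV shipped with the package."""
    return Path(resources.files("cardioscreen").joinpath("data/constituents.csv"))


def _parse_fragments(cell: str) -> tuple[tuple[float, str], ...]:
    if not cell or not cell.strip():
        return ()
    out = []
    for item in cell.split(";"):
        mz, _, label = item.partition("|")
        out.append((float(mz), label))
    return tuple(out)


def load_catalog(path: str | Path | None = None) -> list[CompoundRecord]:
    """Read a catalog CSV into :class:`CompoundRecord` objects.

    With no argument, loads the packaged 71-peak table. Raises on missing
    columns, duplicate peak numbers, or an empty table.
    """
    src = Path(path) if path is not None else packaged_catalog_path()
    df = pd.read_csv(src, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {src} missing required columns: {missing}")
    if df.empty:
        raise ValueError(f"catalog {src} contains no rows")
    peaks = df["peak_no"].astype(int)
    if peaks.duplicated().any():
        dupes = sorted(peaks[peaks.duplicated()].unique())
        raise ValueError(f"duplicate peak_no values: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        formula = parse_formula(row.formula) if row.formula.strip() else None
        err = row.error_ppm.strip()
        try:
            printed = float(err)
        except ValueError:
            printed = None  # table prints "None" for unverifiable rows
        records.append(CompoundRecord(
            peak_no=int(row.peak_no),
            t_r=float(row.tr_min),
            name=row.name,
            detected_mz=float(row.detected_mz),
            formula=formula,
            printed_error_ppm=printed,
            fragments=_parse_fragments(row.fragments),
            source=row.source.strip() or None,
        ))
    return records


def load_known_discrepancies(path: str | Path | None = None) -> pd.DataFrame:
    """Sidecar of rows whose printed name/formula/mass conflict internally."""
    if path is None:
        path = Path(resources.files("cardioscreen").joinpath(
            "data/known_discrepancies.csv"))
    return pd.read_csv(path)


def select_adduct(
    formula: MolecularFormula,
    detected_mz: float,
    search_ppm: float = 20.0,
    adducts: Sequence[str] = ADDUCT_ORDER,
) -> tuple[str, float, float] | None:
    """First adduct (in order) whose theoretical m/z is within ``search_ppm``.

    Returns ``(adduct, theoretical_mz, ppm)`` or None. The deprotonated ion
    is tried before the formate adduct because the detected column of the
    table holds the FA adduct only for a minority of rows (e.g. lobetyol).
    """
    mass = monoisotopic_mass(formula)
    for adduct in adducts:
        theo = adduct_mz(mass, adduct)
        ppm = ppm_error(detected_mz, theo)
        if abs(ppm) <= search_ppm:
            return adduct, theo, ppm
    return None


def validate_catalog(
    catalog: Iterable[CompoundRecord],
    ppm_round: int = 1,
    search_ppm: float = 20.0,
) -> pd.DataFrame:
    """Recompute every row's mass error and compare with the printed value.

    Returns a report with one row per record: selected adduct, theoretical
    m/z, recomputed signed ppm (rounded to ``ppm_round`` decimals), the
    printed ppm, and a status in {verified, mismatch, unverifiable,
    no_formula}. A row is *verified* when |recomputed - printed| <= 0.05
    after rounding; *unverifiable* when no candidate adduct lands within
    the ``search_ppm`` window (or the table prints no numeric error);
    problems are reported, never raised.
    """
    rows = []
    for rec in catalog:
        entry = {
            "peak_no": rec.peak_no,
            "name": rec.name,
            "adduct": None,
            "theoretical_mz": None,
            "recomputed_ppm": None,
            "printed_ppm": rec.printed_error_ppm,
            "status": "no_formula",
        }
        if rec.formula is not None:
            hit = select_adduct(rec.formula, rec.detected_mz, search_ppm)
            if hit is None:
                entry["status"] = "unverifiable"
            else:
                adduct, theo, ppm = hit
                recomputed = round_half_away(ppm, ppm_round)
                entry.update(adduct=adduct, theoretical_mz=theo,
                             recomputed_ppm=recomputed)
                if rec.printed_error_ppm is None:
                    entry["status"] = "unverifiable"
                elif abs(recomputed - rec.printed_error_ppm) <= 0.05:
                    entry["status"] = "verified"
                else:
                    entry["status"] = "mismatch"
        rows.append(entry)
    return pd.DataFrame(rows)


def annotate_fragment(
    precursor: MolecularFormula | str,
    fragment_mz: float,
    max_losses: int = 3,
    tol: float = 0.02,
    loss_library: dict[str, float] | None = None,
) -> FragmentAnnotation:
    """Explain a fragment as the precursor [M-H]- minus a multiset of losses.

    Searches loss multisets of increasing cardinality (0..``max_losses``,
    losses reusable) and returns the smallest-cardinality composition with
    |[M-H]- - sum(losses) - fragment| <= ``tol`` Da, ties broken by the
    smallest absolute residual. Tolerance is absolute (Da) because printed
    fragment masses in unit-resolution MS/MS columns wander by ~10 ppm.
    """
    if isinstance(precursor, str):
        precursor = parse_formula(precursor)
    library = loss_library if loss_library is not None else LOSS_LIBRARY
    base = adduct_mz(monoisotopic_mass(precursor), "[M-H]-")
    names = sorted(library)
    for k in range(max_losses + 1):
        best: tuple[float, tuple[str, ...]] | None = None
        for combo in itertools.combinations_with_replacement(names, k):
            theo = base - sum(library[n] for n in combo)
            delta = theo - fragment_mz
            if abs(delta) <= tol and (best is None or abs(delta) < abs(best[0])):
                best = (delta, combo)
        if best is not None:
            delta, combo = best
            return FragmentAnnotation(
                fragment_mz=fragment_mz,
                loss_composition=combo,
                theoretical_mz=fragment_mz + delta,
                delta_da=delta,
                matched=True,
            )
    return FragmentAnnotation(
        fragment_mz=fragment_mz,
        loss_composition=(),
        theoretical_mz=base,
        delta_da=base - fragment_mz,
        matched=False,
    )
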