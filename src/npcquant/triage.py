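"""Docking-score triage: binding efficiency, hit calling, and Vina output parsing.

A virtual screen yields one binding energy per compound (kcal/mol, more
negative = stronger predicted binding).  This module normalizes those
energies by molecular size (binding efficiency per heavy atom), calls hit
compounds against a natural-ligand reference energy with an inclusive
threshold, and parses AutoDock Vina result files (PDBQT remarks or the
log-style affinity table).

A packaged worked example — twelve compounds (ten candidates plus the
cholesterol and 25-hydroxycholesterol references) with their screen
energies and printed efficiencies — is available via
:func:`load_reference_table`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, SmilesParseError, ValidationError, VinaParseError

__all__ = [
    "CompoundRecord",
    "HitCriterion",
    "DockingModeList",
    "heavy_atom_count",
    "ligand_efficiency",
    "verify_efficiency_table",
    "select_hits",
    "rank_compounds",
    "parse_vina_result",
    "serialize_modes",
    "load_compound_table",
    "load_reference_table",
    "CHOLESTEROL_REFERENCE_ENERGY",
]

#: Docking energy of the cholesterol reference ligand (kcal/mol).
CHOLESTEROL_REFERENCE_ENERGY = -11.3


def heavy_atom_count(structure: str) -> int:
    """Count non-hydrogen atoms in a molecule given as a SMILES string.

    Parameters
    ----------
    structure:
        SMILES string.

    Returns
    -------
    int
        Number of heavy (non-hydrogen) atoms.

    Raises
    ------
    SmilesParseError
        If the string does not parse as a molecule.
    """
    from rdkit import Chem  # deferred: RDKit import is slow

    if not isinstance(structure, str) or not structure.strip():
        raise SmilesParseError(structure)
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise SmilesParseError(structure)
    return mol.GetNumHeavyAtoms()


def ligand_efficiency(binding_energy: float, n_heavy: int) -> float:
    """Binding efficiency: docking energy divided by heavy-atom count.

    Parameters
    ----------
    binding_energy:
        Docking binding energy in kcal/mol (typically negative).
    n_heavy:
        Heavy-atom (non-hydrogen) count, at least 1.

    Returns
    -------
    float
        Energy per heavy atom (kcal/mol per heavy atom); same sign as
        ``binding_energy``.
    """
    if n_heavy < 1:
        raise DomainError(f"heavy-atom count must be >= 1, got {n_heavy}")
    if not math.isfinite(binding_energy):
        raise DomainError(f"binding energy must be finite, got {binding_energy}")
    return binding_energy / n_heavy


@dataclass
class CompoundRecord:
    """One screened compound.

    Attributes
    ----------
    compound_id:
        Stable identifier (e.g. a DrugBank accession).
    name:
        Human-readable compound name.
    binding_energy:
        Docking binding energy in kcal/mol.
    smiles:
        Structure as SMILES; optional if ``heavy_atom_count`` is given.
    heavy_atom_count:
        Non-hydrogen atom count; derived from ``smiles`` on first access
        if absent.
    binding_efficiency:
        Printed efficiency (kcal/mol per heavy atom), as reported in a
        source table; kept separate from the computed value so the two
        can be cross-checked.
    efficiency_decimals:
        Number of decimals the printed efficiency carries; used for the
        half-ULP comparison in :func:`verify_efficiency_table`.
    is_reference:
        True for natural-ligand reference rows (excluded from hit lists).
    """

    compound_id: str
    name: str
    binding_energy: float
    smiles: str | None = None
    heavy_atom_count: int | None = None
    binding_efficiency: float | None = None
    efficiency_decimals: int | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.binding_energy is None or not math.isfinite(self.binding_energy):
            raise ValidationError(
                f"compound {self.compound_id!r}: binding energy missing or non-finite"
            )
        if self.heavy_atom_count is not None and self.heavy_atom_count < 1:
            raise ValidationError(
                f"compound {self.compound_id!r}: heavy-atom count must be >= 1"
            )

    def n_heavy(self) -> int:
        """Heavy-atom count, computed from the SMILES if not stored."""
        if self.heavy_atom_count is None:
            if self.smiles is None:
                raise ValidationError(
                    f"compound {self.compound_id!r}: neither heavy-atom count nor SMILES given"
                )
            self.heavy_atom_count = heavy_atom_count(self.smiles)
        return self.heavy_atom_count

    def efficiency(self) -> float:
        """Computed binding efficiency (energy / heavy atoms)."""
        return ligand_efficiency(self.binding_energy, self.n_heavy())


@dataclass(frozen=True)
class HitCriterion:
    """Hit-calling rule: at least as strong a binding energy as the reference.

    ``inclusive`` is fixed true: compounds tying the reference energy are
    hits.
    """

    reference_energy: float = CHOLESTEROL_REFERENCE_ENERGY
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.inclusive:
            raise ValidationError("hit criterion is inclusive by definition")

    def is_hit(self, binding_energy: float) -> bool:
        return binding_energy <= self.reference_energy


@dataclass
class DockingModeList:
    """Parsed docking result: ordered binding modes with affinities.

    Mode 1 (the first entry) carries the best (most negative) affinity.
    """

    modes: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValidationError("mode list must be non-empty")
        affinities = [a for _, a in self.modes]
        if any(affinities[i] > affinities[i + 1] for i in range(len(affinities) - 1)):
            raise ValidationError("mode affinities must be non-decreasing")

    @property
    def best_affinity(self) -> float:
        return self.modes[0][1]


def verify_efficiency_table(records: Sequence[CompoundRecord]) -> list[bool]:
    """Check each record's printed efficiency against energy / heavy atoms.

    A row passes when the recomputed efficiency is within half a unit of
    the last printed decimal of the row's stated efficiency.

    Raises
    ------
    ValidationError
        If any record lacks the printed efficiency, its decimal count, or
        the means to obtain a heavy-atom count; the message lists the
        offending row ids.
    """
    missing = [
        r.compound_id
        for r in records
        if r.binding_efficiency is None
        or r.efficiency_decimals is None
        or (r.heavy_atom_count is None and r.smiles is None)
    ]
    if missing:
        raise ValidationError(f"rows missing required fields: {missing}")
    results = []
    for rec in records:
        tol = 0.5 * 10.0 ** (-rec.efficiency_decimals)
        results.append(abs(rec.efficiency() - rec.binding_efficiency) <= tol)
    return results


def select_hits(
    records: Sequence[CompoundRecord], criterion: HitCriterion
) -> list[CompoundRecord]:
    """Return the records meeting the hit criterion, strongest binder first.

    Ordering: binding energy ascending, ties broken by binding efficiency
    ascending, then by compound id.  Reference rows are never returned.
    An empty input yields an empty hit list.
    """
    hits = [
        r
        for r in records
        if not r.is_reference and criterion.is_hit(r.binding_energy)
    ]
    return sorted(
        hits, key=lambda r: (r.binding_energy, r.efficiency(), r.compound_id)
    )


def rank_compounds(
    records: Sequence[CompoundRecord],
    criterion: HitCriterion | None = None,
) -> pd.DataFrame:
    """Rank-ordered report table of a screen.

    Columns: ``rank``, ``compound_id``, ``name``, ``binding_energy``,
    ``binding_efficiency`` (computed), and — when a criterion is given —
    ``is_hit``.  Sorted by energy ascending, then efficiency, then id.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "compound_id": rec.compound_id,
                "name": rec.name,
                "binding_energy": rec.binding_energy,
                "binding_efficiency": rec.efficiency(),
                "is_reference": rec.is_reference,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        cols = ["rank", "compound_id", "name", "binding_energy", "binding_efficiency"]
        return pd.DataFrame(columns=cols)
    table = table.sort_values(
        ["binding_energy", "binding_efficiency", "compound_id"],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", range(1, len(table) + 1))
    if criterion is not None:
        table["is_hit"] = [
            (not ref) and criterion.is_hit(e)
            for ref, e in zip(table["is_reference"], table["binding_energy"])
        ]
    return table


_PDBQT_RESULT = re.compile(
    r"^REMARK VINA RESULT:\s+(?P<aff>\S+)\s+\S+\s+\S+\s*$"
)
# log dialect rows look like "   1       -11.4      0.000      0.000"
_LOG_ROW = re.compile(r"^\s*(?P<mode>\d+)\s+(?P<aff>-?\d+(?:\.\d+)?)\s+\S+\s+\S+\s*$")


def parse_vina_result(text: str, dialect: str = "pdbqt") -> DockingModeList:
    """Parse AutoDock Vina output into an ordered mode list.

    Parameters
    ----------
    text:
        File content.
    dialect:
        ``"pdbqt"`` scans for ``REMARK VINA RESULT`` lines (one per docked
        mode); ``"log"`` reads the terminal affinity table.  Any other
        value is rejected.

    Raises
    ------
    VinaParseError
        If no result record is found or an affinity fails to parse (the
        message carries the 1-based line number).
    """
    if dialect not in ("pdbqt", "log"):
        raise VinaParseError(f"unsupported dialect {dialect!r}")
    modes: list[tuple[int, float]] = []
    if dialect == "pdbqt":
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.startswith("REMARK VINA RESULT"):
                m = _PDBQT_RESULT.match(line)
                if not m:
                    raise VinaParseError(f"malformed result record at line {lineno}")
                try:
                    aff = float(m.group("aff"))
                except ValueError:
                    raise VinaParseError(
                        f"non-numeric affinity at line {lineno}: {m.group('aff')!r}"
                    ) from None
                modes.append((len(modes) + 1, aff))
    else:
        in_table = False
        for lineno, line in enumerate(text.splitlines(), start=1):
            if re.match(r"^-{4,}\+?", line.strip()):
                in_table = True
                continue
            if in_table:
                m = _LOG_ROW.match(line)
                if m:
                    modes.append((int(m.group("mode")), float(m.group("aff"))))
                elif modes:
                    break  # table ended
    if not modes:
        raise VinaParseError("no result record found")
    return DockingModeList(modes=modes)


def serialize_modes(result: DockingModeList) -> str:
    """Render a mode list back to PDBQT-style result remarks (affinities only)."""
    return "\n".join(
        f"REMARK VINA RESULT:    {aff:>8g}      0.000      0.000"
        for _, aff in result.modes
    )


def _printed_decimals(text: str) -> int:
    text = text.strip()
    return len(text.split(".")[1]) if "." in text else 0


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Load a compound table from CSV/TSV.

    Required columns: ``compound_id``, ``name``, ``binding_energy``, and at
    least one of ``smiles`` / ``heavy_atoms``.  Optional:
    ``binding_efficiency`` (printed value; decimal precision is inferred
    from the text) and ``role`` (``reference`` rows are flagged).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    required = {"compound_id", "name", "binding_energy"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"compound table missing columns: {sorted(missing)}")
    if "smiles" not in raw.columns and "heavy_atoms" not in raw.columns:
        raise ValidationError("compound table needs a 'smiles' or 'heavy_atoms' column")
    records = []
    for _, row in raw.iterrows():
        be_text = row.get("binding_efficiency")
        has_be = isinstance(be_text, str) and be_text.strip() != ""
        n_heavy = row.get("heavy_atoms")
        records.append(
            CompoundRecord(
                compound_id=row["compound_id"],
                name=row["name"],
                binding_energy=float(row["binding_energy"]),
                smiles=row.get("smiles") if isinstance(row.get("smiles"), str) else None,
                heavy_atom_count=int(n_heavy) if isinstance(n_heavy, str) and n_heavy.strip() else None,
                binding_efficiency=float(be_text) if has_be else None,
                efficiency_decimals=_printed_decimals(be_text) if has_be else None,
                is_reference=str(row.get("role", "")).strip().lower() == "reference",
            )
        )
    return records


def load_reference_table() -> list[CompoundRecord]:
    """The packaged worked example: ten candidates plus two reference sterols."""
    with resources.as_file(
        resources.files("npcquant").joinpath("data/top_hits.csv")
    ) as p:
        return load_compound_table(p)
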