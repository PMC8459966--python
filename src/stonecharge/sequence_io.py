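"""Reading and writing protein sequences, annotation tables and metrics tables.

FASTA input goes through Biopython; delimited tables through pandas. Headers
in the UniProt ``db|ACCESSION|ID`` grammar are recognised and split into
accession and identifier; any other header is used whole as the identifier.

Annotation tables mirror the shape of published protein-list tables:
one row per protein with an identifier, optional accession/name/group/
abundance columns, and optionally precomputed D/E/K/R counts plus length so
downstream charge metrics can run without sequences. Column matching is
case-insensitive; TSV or CSV dialect is picked from the file extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .charge_metrics import VALID_RESIDUES, ChargeProfile, ResidueCounts

__all__ = [
    "Group",
    "ProteinRecord",
    "ProteinSet",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_metrics_table",
]


class Group(str, Enum):
    """Phase-preference label for a protein."""

    MPP = "MPP"
    UPP = "UPP"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identity, optional sequence, group label, abundances.

    ``relative_abundance`` is the generic per-set abundance (percent of the
    sample's protein mass); ``matrix_abundance`` / ``urine_abundance`` hold
    the paired means needed for phase-preference assignment. ``counts``
    carries precomputed residue tallies for table-only workflows.
    """

    identifier: str
    sequence: str = ""
    accession: str = ""
    name: str = ""
    group: Group = Group.UNASSIGNED
    relative_abundance: float | None = None
    matrix_abundance: float | None = None
    urine_abundance: float | None = None
    counts: ResidueCounts | None = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("ProteinRecord requires a non-empty identifier")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.identifier!r}: invalid residue character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def with_group(self, group: Group) -> "ProteinRecord":
        return replace(self, group=group)


@dataclass
class ProteinSet:
    """Ordered collection of records with unique identifiers."""

    records: list[ProteinRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.identifier in seen:
                raise ValueError(f"duplicate identifier {rec.identifier!r}")
            seen.add(rec.identifier)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, identifier: str) -> bool:
        return any(r.identifier == identifier for r in self.records)

    def get(self, identifier: str) -> ProteinRecord:
        for rec in self.records:
            if rec.identifier == identifier:
                return rec
        raise KeyError(identifier)

    @property
    def identifiers(self) -> list[str]:
        return [r.identifier for r in self.records]


def _clean_sequence(raw: str, identifier: str) -> str:
    """Uppercase, strip whitespace/gaps/stops, validate the alphabet."""
    seq = "".join(raw.split()).upper().replace("*", "").replace("-", "")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"record {identifier!r}: invalid residue character(s) "
            f"{''.join(sorted(bad))!r}"
        )
    return seq


def _parse_header(header_id: str, description: str) -> tuple[str, str, str]:
    """Split a FASTA header into (identifier, accession, name)."""
    parts = header_id.split("|")
    if len(parts) == 3 and parts[1] and parts[2]:
        accession, identifier = parts[1], parts[2]
    else:
        accession, identifier = "", header_id
    # description repeats the id token; anything after it is the free-text name
    name = description[len(header_id):].strip() if description.startswith(header_id) else description
    return identifier, accession, name


def read_fasta(path: str | Path, label: str = "") -> ProteinSet:
    """Parse a FASTA file into a :class:`ProteinSet`.

    Multi-line sequences are joined, lowercase letters uppercased, ``*`` and
    ``-`` stripped. UniProt-style three-field headers yield accession and
    identifier; other headers become the identifier verbatim.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        identifier, accession, name = _parse_header(entry.id, entry.description)
        seq = _clean_sequence(str(entry.seq), identifier)
        records.append(
            ProteinRecord(
                identifier=identifier, sequence=seq,
                accession=accession, name=name,
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return ProteinSet(records=records, label=label or path.stem)


def write_fasta(proteins: ProteinSet | Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, reconstructing UniProt-style headers."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in proteins:
            if rec.accession:
                header = f"sp|{rec.accession}|{rec.identifier}"
            else:
                header = rec.identifier
            if rec.name:
                header = f"{header} {rec.name}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation and metrics tables

_COLUMN_ALIASES = {
    "identifier": {"id", "identifier", "abbreviation", "abbrev", "protein"},
    "accession": {"accession", "acc", "accession_number"},
    "name": {"name", "protein_name", "description"},
    "group": {"group", "set", "phase"},
    "sequence": {"sequence", "seq"},
    "relative_abundance": {"relative_abundance", "abundance", "rel_abundance"},
    "matrix_abundance": {"matrix_abundance", "matrix_mean_abundance"},
    "urine_abundance": {"urine_abundance", "urine_mean_abundance"},
    "n_D": {"d", "n_d", "asp"},
    "n_E": {"e", "n_e", "glu"},
    "n_K": {"k", "n_k", "lys"},
    "n_R": {"r", "n_r", "arg"},
    "length": {"length", "residues", "total_residues", "n_residues"},
}


def _map_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map canonical field names to actual column names, case-insensitively."""
    lookup = {c.strip().lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lookup:
                mapping[canonical] = lookup[alias]
                break
    return mapping


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_annotation_table(path: str | Path, label: str = "") -> ProteinSet:
    """Read a TSV/CSV protein annotation table into a :class:`ProteinSet`.

    Requires an identifier column. When all of the D/E/K/R count columns and
    a length column are present, each record carries precomputed
    :class:`ResidueCounts` usable downstream without a sequence.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    cols = _map_columns(df.columns)
    if "identifier" not in cols:
        raise ValueError(f"{path}: no identifier column found")

    count_fields = ("n_D", "n_E", "n_K", "n_R", "length")
    have_counts = all(f in cols for f in count_fields)

    def _num(row_idx: int, field_name: str, text: str) -> float | None:
        text = text.strip()
        if text in ("", "NA", "nan", "None"):
            return None
        try:
            return float(text)
        except ValueError:
            raise ValueError(
                f"{path} row {row_idx + 2}: non-numeric value {text!r} "
                f"in column {field_name!r}"
            ) from None

    records: list[ProteinRecord] = []
    for i, row in df.iterrows():
        ident = row[cols["identifier"]].strip()
        counts = None
        if have_counts:
            vals = {}
            for f in count_fields:
                v = _num(i, cols[f], row[cols[f]])
                if v is None or v != int(v):
                    raise ValueError(
                        f"{path} row {i + 2}: count column {cols[f]!r} "
                        f"must be a non-negative integer, got {row[cols[f]]!r}"
                    )
                vals[f] = int(v)
            counts = ResidueCounts(**vals)
        group = Group.UNASSIGNED
        if "group" in cols and row[cols["group"]].strip():
            group = Group(row[cols["group"]].strip().upper())
        seq = ""
        if "sequence" in cols:
            seq = _clean_sequence(row[cols["sequence"]], ident)
        records.append(
            ProteinRecord(
                identifier=ident,
                sequence=seq,
                accession=row[cols["accession"]].strip() if "accession" in cols else "",
                name=row[cols["name"]].strip() if "name" in cols else "",
                group=group,
                relative_abundance=_num(i, "relative_abundance", row[cols["relative_abundance"]])
                if "relative_abundance" in cols else None,
                matrix_abundance=_num(i, "matrix_abundance", row[cols["matrix_abundance"]])
                if "matrix_abundance" in cols else None,
                urine_abundance=_num(i, "urine_abundance", row[cols["urine_abundance"]])
                if "urine_abundance" in cols else None,
                counts=counts,
            )
        )
    return ProteinSet(records=records, label=label or path.stem)


METRICS_COLUMNS = [
    "id", "accession", "length", "D", "E", "K", "R",
    "total_charge", "net_charge", "total_charge_pct", "net_charge_pct",
]


def write_metrics_table(
    profiles: Sequence[tuple[ProteinRecord, ChargeProfile]],
    path: str | Path,
) -> None:
    """Write per-protein charge metrics as a TSV (or CSV by extension).

    Percentages are rounded to one decimal at write-out only; integer count
    fields round-trip exactly through :func:`read_annotation_table`.
    """
    if not profiles:
        raise ValueError("no profiles to write")
    path = Path(path)
    rows = []
    for rec, prof in profiles:
        c = prof.counts
        rows.append({
            "id": rec.identifier,
            "accession": rec.accession,
            "length": c.length,
            "D": c.n_D, "E": c.n_E, "K": c.n_K, "R": c.n_R,
            "total_charge": prof.total_charge,
            "net_charge": prof.net_charge,
            "total_charge_pct": f"{prof.total_charge_pct:.1f}",
            "net_charge_pct": f"{prof.net_charge_pct:.1f}",
        })
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )
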