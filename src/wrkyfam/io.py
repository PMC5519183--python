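"""Readers and writers for the family-analysis pipeline.

Handles protein/promoter FASTA, the tab-separated family annotation table
(one row per WRKY gene: heptapeptide(s), zinc-finger type, group, physical
properties, gene structure), and family-level summary statistics.  A
transcription of the published potato WRKY roster (79 genes) ships with the
package as ``data/table1.tsv`` and doubles as test oracle and demo input.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

VALID_GROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")
CANONICAL_HEPTAPEPTIDE = "WRKYGQK"

#: column order of the family annotation table (and of the packaged fixture)
TABLE_COLUMNS = [
    "Name",
    "Locus",
    "Chromosome",
    "Heptapeptide",
    "ZincFingerType",
    "DomainCount",
    "Group",
    "pI",
    "Mw_kDa",
    "ProteinLength_aa",
    "CDSLength_bp",
    "ExonCount",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class GeneRecord:
    """One gene of the family: identity, placement and optional sequence.

    Coordinates are 1-based inclusive base pairs.  ``chr00`` is a valid label
    meaning "not placed on any chromosome"; such genes are excluded from
    positional analyses (duplication calling) but kept everywhere else.
    """

    gene_id: str
    locus_id: str = ""
    chromosome: str = ""
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    protein_seq: Optional[str] = None
    cds_length: Optional[int] = None
    exon_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.protein_seq is not None:
            bad = set(self.protein_seq.upper()) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.gene_id}: non-standard residues {sorted(bad)}"
                )
        if self.exon_count is not None and self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")


@dataclass
class AnnotationRow:
    """One row of the family annotation table.

    ``heptapeptides`` holds one 7-mer per WRKY domain (two for the
    two-domain Group I genes, written slash-separated in the file).  A row is
    a *heptapeptide variant* when it has a single domain whose heptapeptide
    differs from the canonical WRKYGQK.
    """

    name: str
    locus: str
    chromosome: str
    heptapeptides: tuple[str, ...]
    finger_type: str
    domain_count: int
    group: str
    pi: float
    mw: float
    protein_length: int
    cds_length: int
    exon_count: int

    def __post_init__(self) -> None:
        if self.domain_count != len(self.heptapeptides):
            raise ValueError(
                f"{self.name}: domain count {self.domain_count} != "
                f"{len(self.heptapeptides)} heptapeptides"
            )
        if self.group not in VALID_GROUPS:
            raise ValueError(f"{self.name}: unknown group label {self.group!r}")

    @property
    def is_variant(self) -> bool:
        """Single-domain record whose heptapeptide deviates from WRKYGQK."""
        return self.domain_count == 1 and any(
            h != CANONICAL_HEPTAPEPTIDE for h in self.heptapeptides
        )

    @property
    def intron_count(self) -> int:
        return self.exon_count - 1


@dataclass
class FamilySummary:
    n_members: int
    group_counts: dict[str, int]
    subgroup_counts: dict[str, int]
    n_variant_heptapeptide: int
    mean_protein_length: int
    min_protein_length: int
    max_protein_length: int
    intron_histogram: dict[int, int] = field(default_factory=dict)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)``.

    Sequences are uppercased; duplicate record ids raise; an empty file
    returns an empty list with a warning.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_row(row: Mapping[str, object], index: int) -> AnnotationRow:
    def intval(col):
        raw = row[col]
        try:
            v = int(raw)
        except (TypeError, ValueError):
            raise ValueError(f"row {index}: non-numeric {col}: {raw!r}") from None
        return v

    def floatval(col):
        raw = row[col]
        try:
            v = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"row {index}: non-numeric {col}: {raw!r}") from None
        if math.isnan(v):
            raise ValueError(f"row {index}: missing {col}")
        return v

    return AnnotationRow(
        name=str(row["Name"]),
        locus=str(row["Locus"]),
        chromosome=str(row["Chromosome"]),
        heptapeptides=tuple(str(row["Heptapeptide"]).split("/")),
        finger_type=str(row["ZincFingerType"]),
        domain_count=intval("DomainCount"),
        group=str(row["Group"]),
        pi=floatval("pI"),
        mw=floatval("Mw_kDa"),
        protein_length=intval("ProteinLength_aa"),
        cds_length=intval("CDSLength_bp"),
        exon_count=intval("ExonCount"),
    )


def load_annotation_table(path) -> list[AnnotationRow]:
    """Load a family annotation table (TSV with the 12 standard columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no records")
    return [_parse_row(row, i) for i, row in df.iterrows()]


def load_packaged_table1() -> list[AnnotationRow]:
    """The packaged 79-gene potato WRKY roster."""
    with resources.as_file(
        resources.files("wrkyfam").joinpath("data/table1.tsv")
    ) as p:
        return load_annotation_table(p)


def packaged_reference_fasta() -> Path:
    """Path to the packaged synthetic labelled reference-domain FASTA."""
    with resources.as_file(
        resources.files("wrkyfam").joinpath("data/references.synthetic.fa")
    ) as p:
        return Path(p)


def summarize_family(rows: Sequence[AnnotationRow]) -> FamilySummary:
    """Family-level summary: group composition, length range, intron histogram.

    The mean protein length is reported as the integer part of the arithmetic
    mean, matching how the roster's summary is conventionally printed.
    """
    if not rows:
        raise ValueError("summarize_family requires at least one row")
    lengths = [r.protein_length for r in rows]
    groups = Counter("I" if r.group == "I" else "III" if r.group == "III" else "II"
                     for r in rows)
    subgroups = Counter(r.group for r in rows if r.group.startswith("II") and r.group != "III")
    introns = Counter(r.intron_count for r in rows)
    return FamilySummary(
        n_members=len(rows),
        group_counts=dict(groups),
        subgroup_counts=dict(subgroups),
        n_variant_heptapeptide=sum(r.is_variant for r in rows),
        mean_protein_length=int(sum(lengths) / len(lengths)),
        min_protein_length=min(lengths),
        max_protein_length=max(lengths),
        intron_histogram=dict(sorted(introns.items())),
    )


def write_family_table(records, assignments, models, path) -> None:
    """Write the 12-column family table for a set of analysed genes.

    Parameters
    ----------
    records : iterable of GeneRecord
        Gene identity and placement.
    assignments : mapping gene_id -> FamilyAssignment
        Group/subgroup plus evidence (heptapeptides, finger types).
    models : mapping gene_id -> mapping
        Per-gene numbers: ``pi``, ``mw_kda``, ``protein_length``,
        ``cds_length``, ``exon_count``.

    pI and Mw are rounded to 2 decimal places on output.
    """
    rows = []
    for rec in records:
        gid = rec.gene_id
        if gid not in assignments:
            raise KeyError(f"no family assignment for {gid!r}")
        if gid not in models:
            raise KeyError(f"no gene model / properties for {gid!r}")
        a = assignments[gid]
        m = models[gid]
        heptas = a.evidence.get("heptapeptides", ())
        fingers = a.evidence.get("finger_types", ())
        label = a.subgroup if a.subgroup != "none" else a.group
        rows.append(
            {
                "Name": gid,
                "Locus": rec.locus_id or gid,
                "Chromosome": rec.chromosome or "chr00",
                "Heptapeptide": "/".join(heptas),
                "ZincFingerType": "/".join(dict.fromkeys(fingers)) or "incomplete",
                "DomainCount": len(heptas),
                "Group": label,
                "pI": f"{float(m['pi']):.2f}",
                "Mw_kDa": f"{float(m['mw_kda']):.2f}",
                "ProteinLength_aa": int(m["protein_length"]),
                "CDSLength_bp": int(m["cds_length"]),
                "ExonCount": int(m["exon_count"]),
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_annotation_rows(rows: Sequence[AnnotationRow], path) -> None:
    """Serialize annotation rows back to the 12-column TSV (round-trip safe)."""
    out = []
    for r in rows:
        out.append(
            {
                "Name": r.name,
                "Locus": r.locus,
                "Chromosome": r.chromosome,
                "Heptapeptide": "/".join(r.heptapeptides),
                "ZincFingerType": r.finger_type,
                "DomainCount": r.domain_count,
                "Group": r.group,
                "pI": f"{r.pi:.2f}",
                "Mw_kDa": f"{r.mw:.2f}",
                "ProteinLength_aa": r.protein_length,
                "CDSLength_bp": r.cds_length,
                "ExonCount": r.exon_count,
            }
        )
    pd.DataFrame(out, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
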