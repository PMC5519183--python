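"""Gene structure and protein physical properties.

Exon/intron statistics come from GFF3 coding structure (CDS features only;
UTR-bearing exons are ignored), with intron phases defined relative to
codon boundaries: an intron falling between two codons is phase 0, one
interrupting a codon after its first or second nucleotide is phase 1 or 2.
The CDS length of a complete model includes the stop codon, so a protein of
``aa`` residues pairs with ``3 * (aa + 1)`` coding base pairs.

Protein properties are computed from first principles: molecular weight as
the sum of average residue masses plus one water, and the isoelectric point
as the pH where the Henderson-Hasselbalch net charge over the termini and
the ionizable side chains (D, E, C, Y, H, K, R) crosses zero, found by
bisection.  The pKa table defaults to the EMBOSS values and is configurable;
different tables shift pI by a few tenths of a pH unit, which is why
published pI columns are treated as reference-only.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import gffutils

# average (isotope-abundance-weighted) residue masses, Da
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# EMBOSS pKa values
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}
POSITIVE_GROUPS = ("Nterm", "K", "R", "H")
NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


@dataclass
class GeneModel:
    """Coding structure of one gene.

    ``exons`` are 1-based inclusive genomic intervals of the CDS pieces, in
    transcription order (already reversed for minus-strand genes).
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon {start}>{end}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def exon_lengths(self) -> list[int]:
        return [end - start + 1 for start, end in self.exons]

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


@dataclass
class ProteinProperties:
    length: int
    mw_kda: float
    pi: float


def intron_phases(model: GeneModel) -> list[int]:
    """Phase of each intron: cumulative coding length before it, mod 3."""
    phases = []
    cumulative = 0
    for length in model.exon_lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)
    return phases


def cds_length_from_protein(aa_length: int) -> int:
    """Coding length in bp of a complete CDS: one codon per residue plus stop."""
    if aa_length < 1:
        raise ValueError(f"protein length must be >= 1, got {aa_length}")
    return 3 * (aa_length + 1)


def protein_length_from_cds(cds_bp: int) -> int:
    if cds_bp < 6 or cds_bp % 3:
        raise ValueError(f"not a complete CDS length: {cds_bp}")
    return cds_bp // 3 - 1


def molecular_weight(seq: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(seq.upper()):
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"non-standard residue {aa!r} at position {pos}"
            ) from None
    return total / 1000.0


def net_charge(seq: str, ph: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH."""
    s = seq.upper()
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in s:
        if aa in ("C", "D", "E", "H", "K", "R", "Y"):
            counts[aa] = counts.get(aa, 0) + 1
    charge = 0.0
    for grp in POSITIVE_GROUPS:
        n = counts.get(grp, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[grp]))
    for grp in NEGATIVE_GROUPS:
        n = counts.get(grp, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[grp] - ph))
    return charge


def isoelectric_point(
    seq: str, pka: Mapping[str, float] = EMBOSS_PKA, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_properties(seq: str, pka: Mapping[str, float] = EMBOSS_PKA) -> ProteinProperties:
    return ProteinProperties(
        length=len(seq),
        mw_kda=molecular_weight(seq),
        pi=isoelectric_point(seq, pka),
    )


def models_from_gff3(path_or_text: str) -> list[GeneModel]:
    """Gene models from GFF3 (gene/mRNA/CDS features, ID/Parent attributes).

    One model per gene, built from the CDS features of its first mRNA.
    Minus-strand CDS intervals are reversed into transcription order.
    """
    text = str(path_or_text)
    if "\n" in text or "\t" in text:
        db = gffutils.create_db(text, ":memory:", from_string=True,
                                merge_strategy="create_unique")
    else:
        db = gffutils.create_db(text, ":memory:", merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        cds = sorted(
            (f.start, f.end)
            for f in db.children(parent, featuretype="CDS")
        )
        if not cds:
            continue
        strand = gene.strand if gene.strand in "+-" else "+"
        if strand == "-":
            cds = cds[::-1]
        models.append(GeneModel(gene_id=gene.id, strand=strand, exons=cds))
    return models


def structure_table(models: Sequence[GeneModel],
                    proteins: Optional[Mapping[str, str]] = None) -> list[dict]:
    """Rows for the structure TSV: counts, phases and, if available, pI/Mw."""
    rows = []
    for m in models:
        row = {
            "gene_id": m.gene_id,
            "exon_count": m.exon_count,
            "intron_count": m.intron_count,
            "phases": ",".join(map(str, intron_phases(m))),
            "cds_bp": m.cds_length,
        }
        if proteins and m.gene_id in proteins:
            props = protein_properties(proteins[m.gene_id])
            row.update(
                aa=props.length,
                mw_kDa=round(props.mw_kda, 2),
                pI=round(props.pi, 2),
            )
        rows.append(row)
    return rows
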