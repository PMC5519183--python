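"""Group and subgroup assignment for WRKY genes.

The family splits into three groups by a purely structural rule: two WRKY
domains -> Group I; one domain with a C2H2 finger -> Group II; one domain
with a C2HC finger -> Group III.  Group II further splits into five
subgroups (IIa-IIe) that are defined phylogenetically; here each Group II
domain is placed by its nearest labelled reference domain under pairwise
global alignment (BLOSUM62, affine gaps), a deterministic stand-in for the
neighbor-joining placement used in family surveys.  Genes whose zinc finger
is incomplete receive Group II provisionally and are flagged; when reference
domains are supplied their group is resolved by the nearest reference's
label instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .domain_scan import HEPTA_LEN, DomainHit
from .io import AnnotationRow

REFERENCE_CLASSES = ("I-N", "I-C", "IIa", "IIb", "IIc", "IId", "IIe", "III")

#: residues spanned by a domain when the finger end is unknown
DOMAIN_FALLBACK_SPAN = 60


@dataclass(frozen=True)
class AlignScoring:
    """Global-alignment scoring shared by classification and tree distances."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


DEFAULT_SCORING = AlignScoring()


def make_aligner(scoring: AlignScoring = DEFAULT_SCORING) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -abs(scoring.gap_open)
    aligner.extend_gap_score = -abs(scoring.gap_extend)
    return aligner


@dataclass
class ReferenceDomain:
    """A labelled domain sequence (heptapeptide through finger end)."""

    ref_id: str
    label: str
    sequence: str

    def __post_init__(self) -> None:
        if self.label not in REFERENCE_CLASSES:
            raise ValueError(
                f"{self.ref_id}: label {self.label!r} not one of {REFERENCE_CLASSES}"
            )


@dataclass
class FamilyAssignment:
    gene_id: str
    group: str  # I | II | III
    subgroup: str = "none"  # IIa..IIe | none
    flagged: bool = False  # True when the finger was incomplete
    evidence: dict = field(default_factory=dict)


def load_references(path) -> list[ReferenceDomain]:
    """Read labelled reference domains from FASTA with ``>ref_id|label`` headers."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"reference header {rec.id!r} lacks '|label'")
        ref_id, label = rec.id.rsplit("|", 1)
        refs.append(ReferenceDomain(ref_id, label, str(rec.seq).upper()))
    if not refs:
        raise ValueError(f"no reference domains in {path}")
    return refs


def assign_group(hits: Sequence[DomainHit]) -> tuple[str, bool]:
    """Structural group rule.  Returns ``(group, flagged)``.

    Two or more domains -> I.  One domain: C2HC finger -> III, C2H2 -> II;
    an incomplete finger gives II provisionally with the flag set, to be
    resolved against references.
    """
    if not hits:
        raise ValueError("not a family member: no WRKY domain hits")
    if len(hits) >= 2:
        return "I", False
    ftype = hits[0].finger_type
    if ftype == "C2HC":
        return "III", False
    if ftype == "C2H2":
        return "II", False
    return "II", True


def extract_domain(seq: str, hit: DomainHit) -> str:
    """Domain region: heptapeptide start through finger end (or +60 residues)."""
    s = seq.upper()
    if hit.finger_span is not None:
        return s[hit.start : hit.finger_span[1] + 1]
    return s[hit.start : hit.start + DOMAIN_FALLBACK_SPAN]


def assign_subgroup(
    hit: DomainHit,
    seq: str,
    refs: Sequence[ReferenceDomain],
    scoring: AlignScoring = DEFAULT_SCORING,
) -> tuple[str, str, float]:
    """Label of the best-scoring reference for this domain.

    Ties are broken toward the lexicographically first ``ref_id`` (the
    reference list is sorted before scoring, so the result does not depend
    on input order).
    """
    if not refs:
        raise ValueError("empty reference set")
    aligner = make_aligner(scoring)
    query = extract_domain(seq, hit)
    best: Optional[tuple[float, str, str]] = None
    for ref in sorted(refs, key=lambda r: r.ref_id):
        score = float(aligner.score(query, ref.sequence))
        if best is None or score > best[0]:
            best = (score, ref.ref_id, ref.label)
    return best[2], best[1], best[0]


def _group_from_label(label: str) -> str:
    if label.startswith("I-"):
        return "I"
    if label == "III":
        return "III"
    return "II"


def classify_family(
    hit_map: Mapping[str, Sequence[DomainHit]],
    seqs: Mapping[str, str],
    refs: Optional[Sequence[ReferenceDomain]] = None,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[FamilyAssignment]:
    """One assignment per gene with at least one domain hit.

    Group I genes are scored on their C-terminal domain; subgroups are
    resolved only when a reference set is supplied.  Genes with incomplete
    fingers keep their provisional group unless references resolve it.
    """
    out = []
    for gene_id, hits in hit_map.items():
        if gene_id not in seqs:
            raise KeyError(f"no sequence for {gene_id!r}")
        group, flagged = assign_group(hits)
        subgroup = "none"
        evidence: dict = {
            "domain_count": len(hits),
            "heptapeptides": tuple(h.heptapeptide for h in hits),
            "finger_types": tuple(h.finger_type for h in hits),
        }
        if refs:
            scoring_hit = hits[-1]  # C-terminal domain for Group I
            label, ref_id, score = assign_subgroup(
                scoring_hit, seqs[gene_id], refs, scoring
            )
            evidence["nearest_reference_id"] = ref_id
            evidence["reference_score"] = score
            if flagged:
                group = _group_from_label(label)
            if group == "II" and label.startswith("II"):
                subgroup = label
        out.append(
            FamilyAssignment(
                gene_id=gene_id,
                group=group,
                subgroup=subgroup,
                flagged=flagged,
                evidence=evidence,
            )
        )
    return out


def group_counts(assignments: Sequence[FamilyAssignment]) -> dict[str, int]:
    return dict(Counter(a.group for a in assignments))


def subgroup_counts(assignments: Sequence[FamilyAssignment]) -> dict[str, int]:
    return dict(Counter(a.subgroup for a in assignments if a.subgroup != "none"))


def hits_from_annotation(row: AnnotationRow) -> list[DomainHit]:
    """Pseudo-hits reconstructed from an annotation row's printed columns.

    Lets the structural group rule be re-applied to a published roster where
    only heptapeptides and finger types (not positions) are recorded.
    """
    hits = []
    for i, hepta in enumerate(row.heptapeptides):
        hits.append(
            DomainHit(
                start=i * DOMAIN_FALLBACK_SPAN,
                heptapeptide=hepta,
                hepta_class="canonical" if hepta == "WRKYGQK" else "variant",
                finger_type=row.finger_type,
            )
        )
    if len(hits) == 1:
        hits[0].terminus = "only"
    elif hits:
        hits[0].terminus = "N"
        for h in hits[1:]:
            h.terminus = "C"
    return hits
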