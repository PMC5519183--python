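"""Promoter cis-regulatory element counting.

Scans ~1.5-kb upstream promoter sequences for stress-related elements
(ABRE, HSE, MBS, TC-rich repeats, TCA-element, W-box by default) given as
IUPAC consensus strings.  Counting is per window position on both strands:
overlapping occurrences all count, and a window whose reverse complement
equals itself (a palindromic hit) is counted once rather than twice.  The
shipped consensus table is configuration, not ground truth — element
definitions differ between prediction services and should be tuned by the
user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DNA_ALPHABET = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    element_name: str
    iupac: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"{self.element_name}: empty motif")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"{self.element_name}: illegal IUPAC characters {sorted(bad)}"
            )


# PlantCARE-style consensus strings; editable via the motif TSV
DEFAULT_MOTIFS = (
    MotifDef("ABRE", "ACGTG"),
    MotifDef("HSE", "AGAANNTTCT"),
    MotifDef("MBS", "CAACTG"),
    MotifDef("TC-rich", "ATTTTCTTCA"),
    MotifDef("TCA-element", "CCATCTTTTT"),
    MotifDef("W-box", "TTGACY"),
)


@dataclass
class CisProfile:
    gene_id: str
    counts: dict[str, int]
    promoter_length: int


class CompiledMotif:
    """Positional matcher for one IUPAC motif (N in the *sequence* never
    matches a constrained motif position; motif N matches any base)."""

    def __init__(self, motif: MotifDef):
        self.motif = motif
        self.sets = [frozenset(IUPAC[c]) for c in motif.iupac.upper()]
        self.rc_sets = [
            frozenset(IUPAC[c]) for c in reverse_complement(motif.iupac.upper())
        ]

    def __len__(self) -> int:
        return len(self.sets)

    def matches_at(self, seq: str, i: int, sets=None) -> bool:
        sets = self.sets if sets is None else sets
        if i + len(sets) > len(seq):
            return False
        return all(seq[i + k] in s for k, s in enumerate(sets))

    def matches_rc_at(self, seq: str, i: int) -> bool:
        """The motif occurs on the reverse strand over window ``[i, i+m)``."""
        return self.matches_at(seq, i, self.rc_sets)


def compile_motif(m: MotifDef) -> CompiledMotif:
    return CompiledMotif(m)


def count_motif(seq: str, motif: MotifDef | CompiledMotif) -> int:
    """Occurrences of one motif in a promoter, per the strand rules above."""
    cm = motif if isinstance(motif, CompiledMotif) else compile_motif(motif)
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in promoter: {sorted(bad)}")
    m = len(cm)
    total = 0
    for i in range(len(s) - m + 1):
        fwd = cm.matches_at(s, i)
        if fwd:
            total += 1
        if cm.motif.both_strands and cm.matches_rc_at(s, i):
            window = s[i : i + m]
            palindromic_same_hit = fwd and reverse_complement(window) == window
            if not palindromic_same_hit:
                total += 1
    return total


def count_elements(
    promoter_seq: str, motifs: Sequence[MotifDef] = DEFAULT_MOTIFS
) -> dict[str, int]:
    compiled = [compile_motif(m) for m in motifs]
    return {cm.motif.element_name: count_motif(promoter_seq, cm) for cm in compiled}


def profile_promoters(
    records: Iterable[tuple[str, str]],
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
) -> tuple[list[CisProfile], dict[str, int]]:
    """Per-promoter element counts plus a genes-with-element summary.

    ``records`` is an iterable of ``(gene_id, promoter_sequence)`` (e.g. the
    output of :func:`wrkyfam.io.read_fasta`).  The summary maps each element
    to the number of promoters containing at least one occurrence.
    """
    profiles = []
    summary = {m.element_name: 0 for m in motifs}
    for gene_id, seq in records:
        counts = count_elements(seq, motifs)
        profiles.append(CisProfile(gene_id, counts, len(seq)))
        for name, c in counts.items():
            if c >= 1:
                summary[name] += 1
    return profiles, summary


def load_motif_table(path) -> list[MotifDef]:
    """Motif TSV: element_name, iupac, both_strands (true/false)."""
    motifs = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            both = True
            if len(parts) >= 3:
                both = parts[2].strip().lower() in ("1", "true", "yes")
            motifs.append(MotifDef(parts[0].strip(), parts[1].strip().upper(), both))
    if not motifs:
        raise ValueError(f"no motifs in {path}")
    return motifs
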