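"""WRKY domain detection in protein sequences.

A WRKY domain is a ~60-residue DNA-binding module built from two parts: a
conserved heptapeptide (canonically WRKYGQK, with a handful of natural
variants such as WRKYGKK or WKKHGSN) and, downstream of it, a zinc finger
whose four metal-coordinating residues follow a spacing signature —
C-X{4,5}-C-X{21,24}-H-X-H for the C2H2 type and C-X7-C-X{23,24}-H-X-C for
the C2HC type.  Detection is a two-tier rule:

* heptapeptides on an exact allow-list (the canonical form plus the known
  variants) are accepted on their own;
* any other window satisfying the weak positional constraint W.K.G.. is a
  *degenerate* candidate and is kept only when a complete zinc finger
  corroborates it.

Matching is case-insensitive; the ambiguity residue X never matches any of
the constrained positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

DEFAULT_ALLOW_LIST = frozenset(
    {
        "WRKYGQK",  # canonical
        "WRKYGKK",
        "WKKYGQK",
        "WRKYGQR",
        "WRKYGEK",
        "WRKCGQK",
        "WRKYGMK",
        "WKKHGSN",
        "WHKCGQK",
        "WIKYGEN",
    }
)

#: positional constraints of the degenerate tier (0-based index -> residue)
DEGENERATE_POSITIONS = {0: "W", 2: "K", 4: "G"}

HEPTA_LEN = 7


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the domain scan.

    ``c2h2_gap1``/``c2h2_gap2`` and the C2HC equivalents are inclusive
    residue-gap windows between consecutive finger residues (gap3 is fixed
    at 1 for both types, i.e. H-X-H / H-X-C).  ``finger_window`` bounds how
    far downstream of a heptapeptide the finger start may lie.
    """

    allow_list: frozenset[str] = DEFAULT_ALLOW_LIST
    c2h2_gap1: tuple[int, int] = (4, 5)
    c2h2_gap2: tuple[int, int] = (21, 24)
    c2hc_gap1: tuple[int, int] = (7, 7)
    c2hc_gap2: tuple[int, int] = (23, 24)
    finger_window: int = 120

    def __post_init__(self) -> None:
        for name in ("c2h2_gap1", "c2h2_gap2", "c2hc_gap1", "c2hc_gap2"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: empty window [{lo},{hi}]")
        for h in self.allow_list:
            if len(h) != HEPTA_LEN:
                raise ValueError(f"allow-list entry {h!r} is not 7 residues")


DEFAULT_CONFIG = ScanConfig()


@dataclass
class DomainHit:
    """One detected WRKY domain.

    ``start`` is the 0-based index of the heptapeptide's first residue.
    ``finger_spacing`` is ``(gap1, gap2, gap3)``, the residue gaps between
    the four finger residues; ``finger_span`` the 0-based inclusive indices
    of the first and last finger residue.  ``terminus`` labels the domain's
    position when a protein carries two domains (N/C) or "only" for a lone
    domain.
    """

    start: int
    heptapeptide: str
    hepta_class: str  # canonical | variant | degenerate
    finger_type: str  # C2H2 | C2HC | incomplete
    finger_spacing: Optional[tuple[int, int, int]] = None
    finger_span: Optional[tuple[int, int]] = None
    terminus: str = "only"


def is_degenerate_heptapeptide(window: str) -> bool:
    """Weak heptapeptide constraint: W at 1, K at 3, G at 5 (1-based)."""
    if len(window) != HEPTA_LEN:
        return False
    return all(window[i] == aa for i, aa in DEGENERATE_POSITIONS.items())


def find_heptapeptides(
    seq: str, cfg: ScanConfig = DEFAULT_CONFIG
) -> list[tuple[int, str, str]]:
    """All candidate heptapeptides in ``seq``, sorted by position.

    Returns ``(index, 7-mer, class)`` triples; class is ``canonical`` for
    WRKYGQK, ``variant`` for other allow-list members, ``degenerate`` for
    windows that only meet the positional constraint.  Overlapping matches
    are all reported.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    out = []
    for i in range(len(s) - HEPTA_LEN + 1):
        w = s[i : i + HEPTA_LEN]
        if w in cfg.allow_list:
            cls = "canonical" if w == "WRKYGQK" else "variant"
        elif is_degenerate_heptapeptide(w):
            cls = "degenerate"
        else:
            continue
        out.append((i, w, cls))
    return out


def _match_finger_at(
    s: str, c1: int, gap1_window, gap2_window, last_residue: str
) -> Optional[tuple[tuple[int, int, int], tuple[int, int]]]:
    """Try to anchor a finger with its first C at index ``c1``.

    Smallest gap1, then smallest gap2, wins so the reported spacing is
    deterministic.  gap3 is fixed at 1.
    """
    if c1 >= len(s) or s[c1] != "C":
        return None
    for g1 in range(gap1_window[0], gap1_window[1] + 1):
        c2 = c1 + g1 + 1
        if c2 >= len(s) or s[c2] != "C":
            continue
        for g2 in range(gap2_window[0], gap2_window[1] + 1):
            h1 = c2 + g2 + 1
            h2 = h1 + 2
            if h2 >= len(s):
                continue
            if s[h1] == "H" and s[h2] == last_residue:
                return (g1, g2, 1), (c1, h2)
    return None


def find_zinc_finger(
    seq: str, from_index: int, cfg: ScanConfig = DEFAULT_CONFIG
):
    """Leftmost zinc finger starting within ``finger_window`` of ``from_index``.

    Returns ``(finger_type, spacing, span)`` or ``("incomplete", None, None)``
    when no complete finger is found.  When both types can be anchored at the
    same first cysteine, C2H2 wins.
    """
    if from_index < 0 or from_index > len(seq):
        raise ValueError(f"from_index {from_index} outside sequence")
    s = seq.upper()
    stop = min(len(s), from_index + cfg.finger_window + 1)
    for c1 in range(from_index, stop):
        if s[c1] != "C":
            continue
        m = _match_finger_at(s, c1, cfg.c2h2_gap1, cfg.c2h2_gap2, "H")
        if m:
            return "C2H2", m[0], m[1]
        m = _match_finger_at(s, c1, cfg.c2hc_gap1, cfg.c2hc_gap2, "C")
        if m:
            return "C2HC", m[0], m[1]
    return "incomplete", None, None


def scan_protein(
    gene_id: str, seq: str, cfg: ScanConfig = DEFAULT_CONFIG
) -> list[DomainHit]:
    """Detect WRKY domains in one protein.

    Allow-list heptapeptides always yield a hit (possibly with an incomplete
    finger); degenerate heptapeptides are retained only when a complete
    finger corroborates them.  Hits are position-sorted; termini are labelled
    N (first) and C (later) when more than one domain is present.
    """
    hits: list[DomainHit] = []
    if not seq:
        return hits
    for idx, hepta, cls in find_heptapeptides(seq, cfg):
        ftype, spacing, span = find_zinc_finger(seq, idx + HEPTA_LEN, cfg)
        if cls == "degenerate" and ftype == "incomplete":
            continue
        hits.append(
            DomainHit(
                start=idx,
                heptapeptide=hepta,
                hepta_class=cls,
                finger_type=ftype,
                finger_spacing=spacing,
                finger_span=span,
            )
        )
    if len(hits) == 1:
        hits[0].terminus = "only"
    elif len(hits) > 1:
        hits[0].terminus = "N"
        for h in hits[1:]:
            h.terminus = "C"
    return hits


def scan_proteome(
    records: Iterable[tuple[str, str]], cfg: ScanConfig = DEFAULT_CONFIG
) -> dict[str, list[DomainHit]]:
    """Scan many proteins; only genes with at least one hit appear.

    Input order is preserved in the returned mapping; duplicate ids raise.
    """
    out: dict[str, list[DomainHit]] = {}
    seen: set[str] = set()
    for gene_id, seq in records:
        if gene_id in seen:
            raise ValueError(f"duplicate protein id {gene_id!r}")
        seen.add(gene_id)
        hits = scan_protein(gene_id, seq, cfg)
        if hits:
            out[gene_id] = hits
    return out


def hits_to_table(hit_map: dict[str, list[DomainHit]]):
    """Flatten a scan result into rows for TSV output (1-based positions)."""
    rows = []
    for gene_id, hits in hit_map.items():
        for h in hits:
            g1, g2, g3 = h.finger_spacing or ("", "", "")
            rows.append(
                {
                    "gene_id": gene_id,
                    "start": h.start + 1,
                    "heptapeptide": h.heptapeptide,
                    "hepta_class": h.hepta_class,
                    "finger_type": h.finger_type,
                    "gap1": g1,
                    "gap2": g2,
                    "gap3": g3,
                    "terminus": h.terminus,
                }
            )
    return rows
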