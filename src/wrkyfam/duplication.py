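"""Gene duplication analysis: tandem clusters and segmental pairs.

Tandem duplication follows the 100-kb rule used in gene-family surveys: two
or more family genes on one chromosome whose chained span gaps are each at
most 100 kb form a cluster.  Chaining is single linkage on gene spans — the
gap between a candidate and the open cluster is measured from the cluster's
maximum end coordinate to the candidate's start (overlapping spans have gap
0), and the 100-kb bound is inclusive — so a multi-gene cluster may stretch
beyond 100 kb end to end.  Unplaced genes (``chr00``) and genes without
coordinates are excluded.

Segmental duplications are not detected here; collinear anchor pairs come
from an external resource (PGDD-style TSV) and are intersected with the
family roster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import GeneRecord

TANDEM_THRESHOLD_BP = 100_000
UNPLACED = "chr00"


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]  # gene ids ordered by start
    gaps: list[int]  # consecutive span gaps, bp (len = members - 1)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs at least 2 members")


@dataclass(frozen=True)
class SegmentalPair:
    gene_a: str
    gene_b: str
    block_id: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")


def tandem_clusters(
    records: Iterable[GeneRecord], threshold_bp: int = TANDEM_THRESHOLD_BP
) -> list[TandemCluster]:
    """Maximal single-linkage chains of >= 2 genes within the gap threshold."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in records:
        if rec.chromosome == UNPLACED or not rec.chromosome:
            continue
        if rec.start is None or rec.end is None:
            warnings.warn(
                f"{rec.gene_id}: missing coordinates, skipped", stacklevel=2
            )
            continue
        by_chrom.setdefault(rec.chromosome, []).append(rec)

    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene_id))
        chain: list[GeneRecord] = []
        gaps: list[int] = []
        max_end = None

        def flush():
            if len(chain) >= 2:
                clusters.append(
                    TandemCluster(chrom, [g.gene_id for g in chain], list(gaps))
                )

        for g in genes:
            if not chain:
                chain, gaps, max_end = [g], [], g.end
                continue
            gap = max(0, g.start - max_end)
            if gap <= threshold_bp:
                chain.append(g)
                gaps.append(gap)
                max_end = max(max_end, g.end)
            else:
                flush()
                chain, gaps, max_end = [g], [], g.end
        flush()
    return clusters


def _parse_anchor_line(line: str, lineno: int) -> tuple[str, str, str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3 or any(not p.strip() for p in parts[:3]):
        raise ValueError(f"malformed anchor line {lineno}: {line.rstrip()!r}")
    return parts[0].strip(), parts[1].strip(), parts[2].strip()


def segmental_pairs(anchors, roster: Iterable[str]) -> list[SegmentalPair]:
    """Anchor pairs whose genes both belong to the family roster.

    ``anchors`` is a path to a TSV of ``block_id, gene_a, gene_b`` (header
    lines starting with '#' ignored) or an iterable of such triples.
    Unordered duplicates are collapsed; the first block id seen is kept.
    """
    roster_set = set(roster)
    if isinstance(anchors, (str, Path)):
        triples = []
        with open(anchors) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                triples.append(_parse_anchor_line(line, lineno))
    else:
        triples = [tuple(t) for t in anchors]

    seen: set[frozenset[str]] = set()
    pairs: list[SegmentalPair] = []
    for block_id, a, b in triples:
        if a == b:
            continue
        if a not in roster_set or b not in roster_set:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        ga, gb = sorted((a, b))
        pairs.append(SegmentalPair(ga, gb, block_id))
    return pairs
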