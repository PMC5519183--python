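"""Seeded generators for every input the pipeline consumes.

Each generator plants known structure — WRKY domain architectures in
proteins, exon/intron layouts and tandem clusters in a genome, element
occurrences in promoters, fold changes in Cq tables — and records it in a
machine-readable truth manifest, so detection and estimation can be tested
by exact recovery.  Protein background residues are drawn from an alphabet
that excludes C, H and W: without tryptophan no accidental heptapeptide can
arise and without Cys/His no accidental zinc finger, which is what makes
exact-recovery assertions valid.  Decoy proteins reintroduce those residues
deliberately.  All randomness flows from one explicit ``numpy`` generator;
nothing consults global RNG state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cis_scan import (
    DEFAULT_MOTIFS,
    IUPAC,
    MotifDef,
    compile_motif,
    count_elements,
    count_motif,
    reverse_complement,
)
from .classify import REFERENCE_CLASSES, ReferenceDomain
from .domain_scan import DEFAULT_CONFIG, HEPTA_LEN, ScanConfig
from .expression import CONTROL_CONDITION

#: protein background alphabet: the 20 standard residues minus C, H, W
BACKGROUND_AA = "ADEFGIKLMNPQRSTVY"
DNA_BASES = "ACGT"

CONDITIONS = ("salt", "heat", "drought", "SA")
TIMEPOINTS = ("3h", "24h")


def _bg_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_AA), size=n))


def _bg_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=n))


# ---------------------------------------------------------------------------
# proteins

@dataclass
class DomainSpec:
    """Plan for one planted WRKY domain."""

    heptapeptide: str = "WRKYGQK"
    finger_type: str = "C2H2"  # C2H2 | C2HC | incomplete
    gaps: tuple[int, int, int] = (4, 22, 1)

    def finger_block(self) -> str:
        if self.finger_type == "incomplete":
            return ""
        g1, g2, g3 = self.gaps
        last = "H" if self.finger_type == "C2H2" else "C"
        # background spacers cannot contain C/H, so the spacing is unambiguous
        return "C" + "A" * g1 + "C" + "A" * g2 + "H" + "A" * g3 + last


def _check_gaps(spec: DomainSpec, cfg: ScanConfig) -> None:
    g1, g2, g3 = spec.gaps
    if spec.finger_type == "C2H2":
        w1, w2 = cfg.c2h2_gap1, cfg.c2h2_gap2
    elif spec.finger_type == "C2HC":
        w1, w2 = cfg.c2hc_gap1, cfg.c2hc_gap2
    elif spec.finger_type == "incomplete":
        return
    else:
        raise ValueError(f"unknown finger type {spec.finger_type!r}")
    if not (w1[0] <= g1 <= w1[1] and w2[0] <= g2 <= w2[1] and g3 == 1):
        raise ValueError(
            f"gaps {spec.gaps} outside the {spec.finger_type} windows"
        )


def make_protein(
    domains: Sequence[DomainSpec],
    rng: np.random.Generator,
    cfg: ScanConfig = DEFAULT_CONFIG,
    lead: tuple[int, int] = (10, 40),
    spacer: tuple[int, int] = (5, 15),
    tail: tuple[int, int] = (10, 40),
) -> tuple[str, list[dict]]:
    """Protein with the given domains planted; returns (sequence, manifest).

    The manifest records, per domain, the heptapeptide start index, the
    finger type and spacing, and the finger span — exactly what the scanner
    should report.
    """
    if not domains:
        raise ValueError("at least one domain spec required")
    for spec in domains:
        if len(spec.heptapeptide) != HEPTA_LEN:
            raise ValueError(f"heptapeptide {spec.heptapeptide!r} not 7 residues")
        _check_gaps(spec, cfg)
    parts = [_bg_protein(rng, int(rng.integers(*lead)))]
    manifest = []
    pos = len(parts[0])
    for k, spec in enumerate(domains):
        hepta_start = pos
        parts.append(spec.heptapeptide)
        pos += HEPTA_LEN
        gap_to_finger = int(rng.integers(*spacer))
        parts.append(_bg_protein(rng, gap_to_finger))
        pos += gap_to_finger
        block = spec.finger_block()
        entry = {
            "start": hepta_start,
            "heptapeptide": spec.heptapeptide,
            "finger_type": spec.finger_type,
        }
        if block:
            entry["finger_spacing"] = list(spec.gaps)
            entry["finger_span"] = [pos, pos + len(block) - 1]
            parts.append(block)
            pos += len(block)
        manifest.append(entry)
        if k < len(domains) - 1:
            inter = int(rng.integers(20, 60))
            parts.append(_bg_protein(rng, inter))
            pos += inter
    parts.append(_bg_protein(rng, int(rng.integers(*tail))))
    return "".join(parts), manifest


def make_decoy(rng: np.random.Generator) -> str:
    """A non-member: a complete zinc finger but no heptapeptide."""
    return (
        _bg_protein(rng, int(rng.integers(20, 60)))
        + DomainSpec().finger_block()
        + _bg_protein(rng, int(rng.integers(20, 60)))
    )


def make_proteome(
    n_wrky: int,
    n_decoys: int,
    rng: np.random.Generator,
    cfg: ScanConfig = DEFAULT_CONFIG,
) -> tuple[list[tuple[str, str]], dict[str, list[dict]]]:
    """Planted WRKY proteins plus finger-only decoys; manifest per member."""
    records = []
    truth: dict[str, list[dict]] = {}
    group_cycle = ["I", "II", "III"]
    for i in range(n_wrky):
        gid = f"wrky{i + 1:03d}"
        group = group_cycle[i % 3]
        if group == "I":
            specs = [DomainSpec(), DomainSpec()]
        elif group == "III":
            specs = [DomainSpec(finger_type="C2HC", gaps=(7, 24, 1))]
        else:
            specs = [DomainSpec()]
        seq, manifest = make_protein(specs, rng, cfg)
        records.append((gid, seq))
        truth[gid] = manifest
    for i in range(n_decoys):
        records.append((f"decoy{i + 1:03d}", make_decoy(rng)))
    return records, truth


# ---------------------------------------------------------------------------
# labelled references and mutated families

def make_reference_set(rng: np.random.Generator) -> list[ReferenceDomain]:
    """One synthetic labelled domain per reference class.

    Classes differ by their random linker residues (and Group III by its
    C2HC finger), giving well-separated alignment neighborhoods.
    """
    refs = []
    for label in REFERENCE_CLASSES:
        finger = (
            DomainSpec(finger_type="C2HC", gaps=(7, 24, 1))
            if label == "III"
            else DomainSpec()
        )
        seq = (
            "WRKYGQK"
            + _bg_protein(rng, 10)
            + finger.finger_block()
            + _bg_protein(rng, 6)
        )
        refs.append(ReferenceDomain(f"SYNREF-{label}", label, seq))
    return refs


def mutate_domain(
    seq: str, rate: float, rng: np.random.Generator, protected: Iterable[int] = ()
) -> str:
    """Substitute residues at the given per-site rate, skipping protected
    positions; replacements come from the C/H/W-free background alphabet."""
    protected = set(protected)
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in BACKGROUND_AA if a != out[i]]
            out[i] = str(rng.choice(choices))
    return "".join(out)


def _motif_positions(ref: ReferenceDomain) -> set[int]:
    """Indices of the heptapeptide and finger residues within a reference."""
    protected = set(range(HEPTA_LEN))
    for i, aa in enumerate(ref.sequence):
        if aa in "CH":
            protected.add(i)
    return protected


def make_family(
    n_genes: int,
    refs: Sequence[ReferenceDomain],
    mutation_rate: float,
    rng: np.random.Generator,
    labels: Optional[Sequence[str]] = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Proteins embedding mutated copies of labelled reference domains.

    Returns the proteome and a gene -> true label map for recovery tests.
    """
    by_label = {r.label: r for r in refs}
    pool = list(labels) if labels else [r.label for r in refs]
    records = []
    truth = {}
    for i in range(n_genes):
        label = pool[int(rng.integers(len(pool)))]
        ref = by_label[label]
        domain = mutate_domain(
            ref.sequence, mutation_rate, rng, _motif_positions(ref)
        )
        seq = _bg_protein(rng, int(rng.integers(10, 30))) + domain + _bg_protein(
            rng, int(rng.integers(10, 30))
        )
        gid = f"fam{i + 1:03d}"
        records.append((gid, seq))
        truth[gid] = label
    return records, truth


# ---------------------------------------------------------------------------
# genome / gene models

@dataclass
class PlacedGene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]  # genomic order
    phases: list[int]  # expected intron phases (transcription order)
    cluster: Optional[int]  # planted cluster index or None


def _random_exon_lengths(rng: np.random.Generator) -> list[int]:
    n_exons = int(rng.integers(1, 7))
    lengths = [int(rng.integers(30, 300)) for _ in range(n_exons)]
    # make the total a codon multiple so the model is complete
    rem = sum(lengths) % 3
    if rem:
        lengths[-1] += 3 - rem
    return lengths


def make_genome(
    n_genes: int,
    n_chromosomes: int,
    cluster_plan: Sequence[int],
    rng: np.random.Generator,
    intra_gap: tuple[int, int] = (1_000, 50_000),
    inter_gap: tuple[int, int] = (500_000, 800_000),
) -> tuple[list[PlacedGene], str]:
    """Place genes on chromosomes with planted tandem clusters.

    ``cluster_plan`` lists cluster sizes (each >= 2); clustered genes use
    intra-cluster span gaps of at most 50 kb and everything else is spaced
    at least 500 kb apart, so the 100-kb tandem rule recovers the plan
    exactly.  Returns the placed genes and a GFF3 document (gene/mRNA/
    exon/CDS features).
    """
    if any(s < 2 for s in cluster_plan):
        raise ValueError("cluster sizes must be >= 2")
    n_clustered = sum(cluster_plan)
    if n_clustered > n_genes:
        raise ValueError("cluster plan exceeds gene count")

    # assignment: clusters first (round-robin over chromosomes), then singletons
    slots: list[tuple[Optional[int], int]] = []  # (cluster id | None, size)
    for ci, size in enumerate(cluster_plan):
        slots.append((ci, size))
    for _ in range(n_genes - n_clustered):
        slots.append((None, 1))

    cursors = {f"chr{c + 1:02d}": 0 for c in range(n_chromosomes)}
    chrom_names = list(cursors)
    placed: list[PlacedGene] = []
    gid = 0
    for si, (cluster_id, size) in enumerate(slots):
        chrom = chrom_names[si % n_chromosomes]
        for k in range(size):
            gid += 1
            gap = (
                int(rng.integers(*intra_gap))
                if cluster_id is not None and k > 0
                else int(rng.integers(*inter_gap))
            )
            start = cursors[chrom] + gap
            exon_lengths = _random_exon_lengths(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for j, length in enumerate(exon_lengths):
                exons.append((pos, pos + length - 1))
                if j < len(exon_lengths) - 1:
                    pos += length + int(rng.integers(80, 2_000))
                else:
                    pos += length
            end = exons[-1][1]
            tx_lengths = (
                exon_lengths if strand == "+" else list(reversed(exon_lengths))
            )
            phases = []
            cum = 0
            for length in tx_lengths[:-1]:
                cum += length
                phases.append(cum % 3)
            placed.append(
                PlacedGene(
                    gene_id=f"g{gid:03d}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    phases=phases,
                    cluster=cluster_id,
                )
            )
            cursors[chrom] = end

    gff_lines = ["##gff-version 3"]
    for g in sorted(placed, key=lambda p: (p.chromosome, p.start)):
        attrs = f"ID={g.gene_id}"
        gff_lines.append(
            f"{g.chromosome}\twrkyfam\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        mrna = f"{g.gene_id}.t1"
        gff_lines.append(
            f"{g.chromosome}\twrkyfam\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        tx_exons = g.exons if g.strand == "+" else list(reversed(g.exons))
        cum = 0
        frames = []
        for s, e in tx_exons:
            frames.append((3 - cum % 3) % 3)
            cum += e - s + 1
        frame_by_iv = dict(zip(tx_exons, frames))
        for i, (s, e) in enumerate(g.exons, 1):
            gff_lines.append(
                f"{g.chromosome}\twrkyfam\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna}.exon{i};Parent={mrna}"
            )
            gff_lines.append(
                f"{g.chromosome}\twrkyfam\tCDS\t{s}\t{e}\t.\t{g.strand}\t"
                f"{frame_by_iv[(s, e)]}\tID={mrna}.cds{i};Parent={mrna}"
            )
    return placed, "\n".join(gff_lines) + "\n"


# ---------------------------------------------------------------------------
# promoters

def _realize_iupac(motif: str, rng: np.random.Generator) -> str:
    return "".join(str(rng.choice(list(IUPAC[c]))) for c in motif.upper())


def _realize_single_hit(m: MotifDef, rng: np.random.Generator) -> str:
    """A concrete instance of ``m`` that counts exactly once in isolation.

    Needed because some consensi (e.g. AGAANNTTCT) are their own reverse
    complement as a pattern: a non-palindromic realization of such a motif
    matches on both strands and counts twice.
    """
    for _ in range(200):
        inst = _realize_iupac(m.iupac, rng)
        if count_motif(inst, m) == 1:
            return inst
    raise ValueError(f"{m.element_name}: no single-hit realization found")


def _clean_background(
    length: int, motifs: Sequence[MotifDef], rng: np.random.Generator
) -> str:
    """Background DNA with zero occurrences of any motif on either strand."""
    seq = list(_bg_dna(rng, length))
    for _ in range(200):
        counts = count_elements("".join(seq), motifs)
        if not any(counts.values()):
            return "".join(seq)
        # resample a window around each first offending position
        s = "".join(seq)
        for m in motifs:
            if counts[m.element_name] == 0:
                continue
            width = len(m.iupac)
            cm = compile_motif(m)
            for i in range(length - width + 1):
                if cm.matches_at(s, i) or (m.both_strands and cm.matches_rc_at(s, i)):
                    for k in range(i, i + width):
                        seq[k] = str(rng.choice(list(DNA_BASES)))
                    break
    raise RuntimeError("could not generate motif-free background")


def make_promoters(
    count_plan: Mapping[str, Mapping[str, int]],
    rng: np.random.Generator,
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    length: int = 1500,
    max_tries: int = 60,
) -> tuple[list[tuple[str, str]], dict[str, dict[str, int]]]:
    """Promoters whose per-element counts equal the plan exactly.

    Each promoter is motif-free background with the requested number of
    concrete element instances planted at non-overlapping positions on
    random strands; the result is verified against the counting rules and
    regenerated on collision.  Raises when a plan cannot be realised.
    """
    by_name = {m.element_name: m for m in motifs}
    records = []
    manifest: dict[str, dict[str, int]] = {}
    for gene_id, plan in count_plan.items():
        unknown = set(plan) - set(by_name)
        if unknown:
            raise ValueError(f"{gene_id}: unknown elements {sorted(unknown)}")
        total_len = sum(len(by_name[e].iupac) * c for e, c in plan.items())
        if total_len > length // 2:
            raise ValueError(f"{gene_id}: plan too dense for {length} bp")
        for _ in range(max_tries):
            seq = _clean_background(length, motifs, rng)
            arr = list(seq)
            occupied: list[tuple[int, int]] = []
            ok = True
            for element, count in plan.items():
                width = len(by_name[element].iupac)
                for _ in range(count):
                    for _try in range(200):
                        pos = int(rng.integers(0, length - width + 1))
                        span = (pos - width + 1, pos + width - 1)
                        if all(
                            span[1] < a or span[0] > b for a, b in occupied
                        ):
                            break
                    else:
                        ok = False
                        break
                    inst = _realize_single_hit(by_name[element], rng)
                    if by_name[element].both_strands and rng.random() < 0.5:
                        inst = reverse_complement(inst)
                    arr[pos : pos + width] = inst
                    occupied.append((pos, pos + width - 1))
                if not ok:
                    break
            if not ok:
                continue
            candidate = "".join(arr)
            counts = count_elements(candidate, motifs)
            expected = {m.element_name: plan.get(m.element_name, 0) for m in motifs}
            if counts == expected:
                records.append((gene_id, candidate))
                manifest[gene_id] = dict(expected)
                break
        else:
            raise ValueError(f"{gene_id}: could not realise element plan {plan}")
    return records, manifest


# ---------------------------------------------------------------------------
# qPCR tables

def make_cq_table(
    fc_plan: Mapping[str, Mapping[tuple[str, str], float]],
    noise_sd: float,
    reps: int,
    rng: np.random.Generator,
    baseline_target: float = 24.0,
    baseline_reference: float = 20.0,
) -> pd.DataFrame:
    """Cq table realising the planted fold changes under Gaussian Cq noise.

    Treated target Cq = baseline - log2(FC) + noise; control target and all
    reference wells sit at their baselines plus noise.  Includes control
    rows for every (gene, timepoint) in the plan.
    """
    rows = []
    for gene_id, plan in fc_plan.items():
        if any(fc <= 0 for fc in plan.values()):
            raise ValueError(f"{gene_id}: fold changes must be positive")
        timepoints = sorted({tp for _, tp in plan})
        for tp in timepoints:
            for rep in range(1, reps + 1):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "condition": CONTROL_CONDITION,
                        "timepoint": tp,
                        "replicate": rep,
                        "cq_target": baseline_target + noise_sd * rng.standard_normal(),
                        "cq_reference": baseline_reference
                        + noise_sd * rng.standard_normal(),
                    }
                )
        for (condition, tp), fc in plan.items():
            for rep in range(1, reps + 1):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "condition": condition,
                        "timepoint": tp,
                        "replicate": rep,
                        "cq_target": baseline_target
                        - float(np.log2(fc))
                        + noise_sd * rng.standard_normal(),
                        "cq_reference": baseline_reference
                        + noise_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full bundle

@dataclass
class Bundle:
    """A complete synthetic study: every pipeline input plus ground truth."""

    seed: int
    proteome: list[tuple[str, str]]
    references: list[ReferenceDomain]
    gff3: str
    genes: list[PlacedGene]
    promoters: list[tuple[str, str]]
    cq: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        from .io import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteome, out / "proteome.fa")
        write_fasta(
            [(f"{r.ref_id}|{r.label}", r.sequence) for r in self.references],
            out / "references.fa",
        )
        (out / "genome.gff3").write_text(self.gff3)
        coords = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chromosome": [g.chromosome for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )
        coords.to_csv(out / "coords.tsv", sep="\t", index=False)
        write_fasta(self.promoters, out / "promoters.fa")
        self.cq.to_csv(out / "cq.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


def make_bundle(
    seed: int,
    n_genes: int = 18,
    n_chromosomes: int = 4,
    cluster_plan: Sequence[int] = (2, 3),
    noise_sd: float = 0.0,
    reps: int = 3,
) -> Bundle:
    """Zero-noise by default: every module's output should equal the manifest."""
    rng = np.random.default_rng(seed)
    refs = make_reference_set(rng)
    by_label = {r.label: r for r in refs}

    subgroups = ["IIa", "IIb", "IIc", "IId", "IIe"]
    proteome = []
    truth_genes: dict[str, dict] = {}
    for i in range(n_genes):
        gid = f"g{i + 1:03d}"
        kind = i % 6  # rotate through architectures
        if kind == 0:
            group, subgroup = "I", "none"
            domain = by_label["I-C"].sequence
            seq = (
                _bg_protein(rng, 15)
                + by_label["I-N"].sequence
                + _bg_protein(rng, 25)
                + domain
                + _bg_protein(rng, 15)
            )
        elif kind == 5:
            group, subgroup = "III", "none"
            seq = (
                _bg_protein(rng, 15)
                + by_label["III"].sequence
                + _bg_protein(rng, 15)
            )
        else:
            group = "II"
            subgroup = subgroups[(kind - 1) % 5]
            seq = (
                _bg_protein(rng, 15)
                + by_label[subgroup].sequence
                + _bg_protein(rng, 15)
            )
        proteome.append((gid, seq))
        truth_genes[gid] = {"group": group, "subgroup": subgroup}

    genes, gff3 = make_genome(n_genes, n_chromosomes, cluster_plan, rng)
    for g in genes:
        truth_genes[g.gene_id]["phases"] = g.phases
        truth_genes[g.gene_id]["cluster"] = g.cluster
        truth_genes[g.gene_id]["chromosome"] = g.chromosome

    count_plan = {}
    for gid in list(truth_genes)[: max(4, n_genes // 3)]:
        count_plan[gid] = {
            "W-box": int(rng.integers(0, 3)),
            "HSE": int(rng.integers(0, 3)),
            "ABRE": int(rng.integers(0, 2)),
        }
    promoters, promoter_truth = make_promoters(count_plan, rng)
    for gid, counts in promoter_truth.items():
        truth_genes[gid]["elements"] = counts

    fc_plan = {}
    for gid in list(truth_genes)[: max(4, n_genes // 3)]:
        fc_plan[gid] = {
            ("salt", "3h"): float(2.0 ** rng.integers(-3, 4)),
            ("heat", "24h"): float(2.0 ** rng.integers(-3, 4)),
        }
        truth_genes[gid]["fold_changes"] = {
            f"{c}:{tp}": fc for (c, tp), fc in fc_plan[gid].items()
        }
    cq = make_cq_table(fc_plan, noise_sd=noise_sd, reps=reps, rng=rng)

    truth = {
        "seed": seed,
        "parameters": {
            "n_genes": n_genes,
            "n_chromosomes": n_chromosomes,
            "cluster_plan": list(cluster_plan),
            "noise_sd": noise_sd,
            "reps": reps,
        },
        "genes": truth_genes,
    }
    return Bundle(seed, proteome, refs, gff3, genes, promoters, cq, truth)
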