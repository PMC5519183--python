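# Methods

This note documents the models, rules and numerical choices behind
`wrkyfam`, and what the synthetic-data validation does and does not show.

## Domain detection

A WRKY domain is detected as a heptapeptide followed by a zinc finger.
Acceptance of the heptapeptide is two-tiered:

1. **Allow-list** (exact): `WRKYGQK` (canonical) plus the nine naturally
   observed variants `WRKYGKK, WKKYGQK, WRKYGQR, WRKYGEK, WRKCGQK, WRKYGMK,
   WKKHGSN, WHKCGQK, WIKYGEN`. These are accepted even without a complete
   finger, because family members with degenerate fingers exist.
2. **Degenerate** (positional): any 7-mer with W, K, G at positions 1, 3, 5.
   Some real variants differ from the canonical form at up to four
   positions, which defeats any simple edit-distance rule, while all known
   forms share those three anchors. A degenerate candidate is kept only
   when a complete zinc finger corroborates it downstream.

The finger is matched by spacing signature: first cysteine, gap1 residues,
second cysteine, gap2 residues, histidine, one residue, then H (C2H2) or C
(C2HC). The windows are the union of all observed per-group signatures —
gap1 ∈ [4,5], gap2 ∈ [21,24] for C2H2; gap1 = 7, gap2 ∈ [23,24] for C2HC —
rather than exact per-group values, because a single group can show both
`CX4CX22HXH` and `CX4CX23HXH`. The search runs at most 120 residues
downstream of the heptapeptide (no window is stated in the survey
literature; 120 covers the ~60-residue domain with slack), takes the
leftmost matching finger start, prefers the smallest gaps at a given start,
and prefers C2H2 over C2HC when both anchor at the same cysteine. Matching
is case-insensitive; the ambiguity code X matches none of the constrained
residues (conservative). When a protein carries two domains they are
labelled N- and C-terminal; with more than two, the first is N and the rest
C (only the one- and two-domain cases occur in practice).

## Classification

Groups are a pure function of domain count and finger type: ≥2 domains → I;
one domain with C2H2 → II; with C2HC → III. A lone domain with an
incomplete finger is provisionally II and flagged; when labelled reference
domains are available, its group is taken from the nearest reference
instead (such genes do occur — four in the potato roster — and the
published table does not say how they were placed).

Subgroups IIa–IIe are phylogenetic, not structural. Instead of rebuilding
the multi-species neighbor-joining tree, each query domain (heptapeptide
start through finger end, or 60 residues when the finger is incomplete) is
assigned the label of its best-scoring reference domain under global
alignment — deterministic, testable, and faithful to how the subgroups are
defined (clustering with labelled references). Group I genes are scored on
their C-terminal domain, the conventional classifier for two-domain
proteins. Scoring uses BLOSUM62 with affine gap penalties (open 10,
extend 1); ties break toward the lexicographically first reference id.
Because no reference sequences can be shipped from external databases, the
packaged reference set (`data/references.synthetic.fa`) is *synthetic* —
deterministic, labelled domain sequences generated by `wrkyfam.synthetic` —
and real Arabidopsis domains can be dropped in via the same
`>ref_id|label` FASTA convention.

## Phylogeny

Pairwise dissimilarity is the p-distance on an optimal global alignment
(same scoring as classification): 1 − identical columns / alignment
columns. This avoids a multiple-sequence alignment dependency; the original
survey's MSA and distance settings are unstated, so no attempt is made to
reproduce its exact tree. Neighbor joining is the standard Saitou–Nei
agglomeration with Q-criterion (n−2)d(i,j) − Σd(i,·) − Σd(j,·), limb
lengths ½d(i,j) ± (r_i−r_j)/(2(n−2)), a deterministic lexicographic
tie-break, and negative limb estimates clamped to zero with a flag on the
tree (standard practice). Bootstrap is not implemented (no replicate count
to reproduce). Trees serialize to Newick; the parser reports character
positions on malformed input. Correctness is checked three ways: exact
topology recovery on additive matrices (NJ is consistent there), agreement
with an exhaustive least-squares search over all 105 six-leaf topologies,
and agreement with scikit-bio's independent NJ implementation.

## Gene structure and protein properties

Intron phase k is the cumulative coding length of the exons before intron
k, mod 3 (phase 0 = between codons; 1/2 = after the first/second
nucleotide). Models come from GFF3 CDS features only, reversed into
transcription order on the minus strand; UTR exons are ignored. A complete
CDS includes its stop codon, so protein length aa pairs with 3·(aa+1) bp —
this relation holds on 78 of the 79 printed roster rows and is how the
roster's CDS column was evidently produced (the one exception is an
internally inconsistent printed row whose molecular weight supports a
different protein length; the fixture transcribes the table as printed).

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), reported in kDa; the ambiguity residue X is an error. The
isoelectric point solves net charge = 0 by bisection on pH ∈ [0,14] to
1e−4, with Henderson–Hasselbalch charges over the termini and D, E, C, Y,
H, K, R side chains. The pKa table defaults to EMBOSS values and is
configurable; published pI columns are treated as reference-only because
different tools' pKa sets shift pI by a few tenths of a unit, and the
original tool is unknown.

## Duplication

Tandem clusters chain genes on one chromosome whose span gaps (next start
minus the running maximum end so far; overlap → 0) are each ≤ 100 kb,
inclusive — single linkage, so a multi-gene cluster may exceed 100 kb end
to end. The running-maximum form (rather than the literal previous gene's
end) is what makes sorted chaining equal to all-pairs single linkage when
spans nest. The gap is between gene boundaries, not midpoints or starts
(the convention is not fully specified in the literature; both the measure
and the threshold are configurable). Unplaced genes (`chr00`) are excluded.
Segmental duplication detection is out of scope: collinear anchor pairs are
consumed from an external TSV and intersected with the family roster,
deduplicating unordered pairs.

## Cis-element counting

Motifs are IUPAC consensus strings matched per window position on both
strands; overlapping occurrences count. A window that matches and is its
own reverse complement is one physical site and counts once; otherwise
forward and reverse hits at the same position count separately. The default
table (ABRE `ACGTG`, HSE `AGAANNTTCT`, MBS `CAACTG`, TC-rich `ATTTTCTTCA`,
TCA-element `CCATCTTTTT`, W-box `TTGACY`) is **configuration, not ground
truth**: prediction services do not publish exact consensi, so the table is
shipped as an editable TSV and reproduction of any published per-gene
counts is explicitly not claimed.

## Relative expression

Technical replicates are averaged on the Cq scale before differencing
(the underlying study design has three technical replicates and no
biological-replicate structure); ΔCt = mean Cq_target − mean Cq_reference,
ΔΔCt = ΔCt_treated − ΔCt_control, fold change = 2^−ΔΔCt, so log₂FC = −ΔΔCt
exactly. Calls: up if FC > 1+ε, down if FC < 1−ε, else unchanged, with
ε = 0.05 by default because a hard 1.0 cutoff flips under infinitesimal
noise. Missing treated groups yield "undetected" cells rather than errors.
No amplification-efficiency correction and no error bars are computed.

Under the synthetic noise model (independent Gaussian Cq noise, sd σ, on
every well), the ΔΔCt estimator is a difference of four replicate means and
has sd σ·√(4/r) for r replicates; recovery tests use normal-theory bounds
derived from that propagation.

## Synthetic data

The generators emulate the study's conditions: proteomes with planted
domain architectures plus finger-only decoys; genomes with 1–6 exons per
gene, intra-cluster span gaps ≤ 50 kb and all other spacings ≥ 500 kb (so
the 100-kb rule recovers plans exactly); 1500-bp promoters with exact
planted element counts; Cq tables with three technical replicates,
baseline Cq 24 (target) / 20 (reference), and configurable noise
(σ = 0.1 cycles in the noisy-recovery tests, a typical technical-replicate
spread). All randomness flows from one explicit seed; same seed, same
bytes.

Two deliberate idealizations make exact-recovery assertions valid, and
bound what passing tests show about real data:

* Protein background is drawn from the 17 residues excluding C, H and W, so
  no accidental heptapeptide or finger can arise; mutation in the
  family-recovery tests substitutes from the same alphabet and leaves the
  planted heptapeptide/finger residues intact, so detection stays anchored
  while the informative linker residues diverge. Real proteomes contain
  near-miss sequences the generator never produces; specificity against
  such decoys is exercised only by the deliberate decoy generator.
* Promoter backgrounds are scrubbed of all configured motifs before
  planting, and planted instances are realized so each contributes exactly
  one count. Real promoters have correlated base composition and motif
  clustering that the uniform background lacks.

No attempt is made at realistic codon usage, GC content or intron length
distributions. Problem sizes in the test suite (proteomes of tens to a few
hundred genes, trees of 4–12 taxa, 200-gene coordinate sets, 100-gene qPCR
panels) were chosen as the smallest sizes at which the checked properties
are non-trivial.

## Known limitations

* Subgroup placement quality depends entirely on the supplied reference
  domains; the shipped synthetic set validates the machinery, not potato
  biology.
* The scanner has no position-specific scoring (no HMM/PSSM); heptapeptide
  forms outside the allow-list and the W·K·G pattern are invisible.
* p-distances on pairwise alignments are not a substitute for an MSA-based
  phylogeny when sequences are highly divergent.
* The published table's pI/Mw columns cannot be reproduced bit-exactly
  (unknown upstream tool); self-consistency and closed-form checks are
  asserted instead.
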