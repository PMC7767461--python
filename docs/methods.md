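# Methods

`mosaictrace` analyses the genomes of *transjugants* — progeny clones of a
mating between two closely related, highly syntenic bacterial strains — and
reconstructs which parent contributed each piece of the genome. The package
follows the deterministic procedure used in parenthood studies of
*Thermus thermophilus* HB27 × HB8 matings: diagnostic SNPs, not
probabilistic painting, are the unit of evidence.

## The analysis model

**Diagnostic panel.** Two syntenic parents that differ at roughly one site
per 124 bp give a dense, regularly spaced set of diagnostic SNPs
(≈ 8–9 SNPs/kbp inside conserved genes). A `DiagnosticSite` is a position
where the parents carry different single-base alleles; the sorted site list
is the coordinate system of the whole analysis. Panels can be built two
ways, which agree exactly on simulated data:

* *from VCFs* — cross-comparison of the two parents' variant sets against a
  common reference. A site is diagnostic when exactly one parent differs
  from the reference, or both differ with different alleles (kept, flagged
  `both_nonref`: the parents still distinguish each other). Positions where
  both parents share the same non-reference allele are non-diagnostic and
  dropped, as are indels and multi-nucleotide records. Laboratory parental
  stocks first have their variants against their own public reference
  masked out (`mask_parental_artifacts`), re-basing the comparison on the
  actual parental sequences.
* *from genomes* — unique shared k-mers (k = 21) are chained collinearly
  (longest increasing subsequence) and inter-anchor segments compared
  column-wise. Segments of unequal length are resolved with a single-gap
  placement that minimizes total mismatches (O(n) on mismatch prefix sums);
  only when that model fits poorly (> max(3, 20% of columns) residual
  mismatches, i.e. likely more than one indel) does an edit-distance
  alignment (edlib) decide. Gap and unaligned columns contribute no sites.
  Sites within a few bp of an insertion junction are genuinely
  alignment-ambiguous; the truth-VCF route is authoritative there, and the
  simulator round-trip test passes exactly under the single-gap rule.

**Classification.** Each progeny variant (called against the clone's
*background* parent) gets exactly one label: `FOREIGN` (panel site carrying
the other parent's allele — evidence of transfer), `SELF` (background
allele; normally implicit, since no record is expected), `AMBIGUOUS` (third
allele at a panel site; reported but never used for segmentation) or
`NOVEL` (off-panel). Undecomposed multi-allelic records are rejected, not
guessed at.

**Segmentation.** FOREIGN sites on a replicon are clustered by single
linkage with a strict gap rule: a new transferred region starts when
consecutive sites are separated by *more than* `gap_threshold` (default
1000 bp, strict inequality). Region bounds are the boundary
SNPs themselves. True recombination tract ends between panel sites are
unobservable, so reported sizes (`last_snp − first_snp + 1`) are inner,
SNP-supported bounds; single-SNP regions have size 1 and a `single_snp`
flag. The selection-marker cassette participates as a virtual foreign site
at its midpoint, so a clone whose only transferred material is the marker
still reports one region — with `n_snps = 0` and `contains_marker` set
(the published tables count such regions while reporting zero SNPs, which
is why marker-only regions are allowed to carry no real sites).

**Gene capture.** Strain-specific (non-homologous) genes are found by
local alignment of each annotated gene against the other genome:
seed-and-extend with exact 15-mer seeds clustered by diagonal band and
validated by edlib, reporting query coverage and identity over the covered
span. A gene is specific when no alignment reaches `min_query_cover`
(default 0.40) at `min_identity`. The published criterion pairs the 40%
cover rule with a zero e-value; e-values are tool- and database-dependent,
so the package uses an identity threshold instead (default 0.99 on the
covered span). For *specificity calls between the two parents themselves*,
whose conserved genes differ by the ~0.8% backbone divergence (≈ 99.2%
identity), a threshold of 0.95 is the appropriate setting and is what the
validation suite uses; 0.99 is kept as the package default because capture
detection in progeny contigs compares identical sequences. Detected hits
carry an insertion mode: `homologous_flank` when a contig flank places
within 5 kbp of a background homologue of the gene's native neighbours
(recombination-arm capture), `transposition` when the flanks place at an
unrelated locus, `unplaced` when less than 200 bp of flank is assessable —
mirroring how a too-short contig prevented localization in the original
study.

**Marker localization.** Reads or contigs that span a cassette end are
split at the junction; the non-cassette portion (≥ 30 bp, inside the
shortest study read of 36 bp) is placed on the background reference —
exactly when possible, via edlib (≤ 10% edits) otherwise, since junction
anchors legitimately carry donor alleles at diagnostic sites. The insertion
interval is the span between the consensus 5′ and 3′ junction placements;
anchors matching multiple loci equally well raise an ambiguous-locus error
listing the candidates. Absence of the cassette in every sequence is a
no-marker signal (`None`), not an error.

**Recruitment.** The fraction of a clone's reads that align to each
parental reference identifies its background parent. A read is recruited
when a full-length placement has at most `max_mismatch_frac` mismatches
(default 0.05 — room for the 0.8% backbone divergence plus read error,
while rejecting reads from non-homologous content). Reads are counted, not
bases; there is no soft-clipping or reverse-strand model (the simulator
emits forward reads; real data should enter via the per-read flag adapter).
The background call is the argmax, flagged inconclusive below a 5-point
margin (observed study margins are ≥ 10). The separation is driven by
strain-specific gene content — reads from genes absent in the other strain
cannot place — not by the SNP divergence, which fits inside the mismatch
budget.

## The simulator

The synthetic module emulates the HB27/HB8 mating system at configurable
scale. All strain content lives on a shared "core" backbone; parent B is
parent A with i.i.d. substitutions at `snp_density` (default 1/124 per bp,
the study's genome-wide density), and each parent receives private ORF-like
gene insertions anchored in intergenic backbone (≥ 500 bp shared flank),
including one IS-like element per parent that serves as the transposition
substrate. Exact coordinate maps between the core, each parent, and each
clone make the emitted truth (VCF, BED, JSON manifest) exact by
construction; a round-trip property test (apply truth variants to either
parent → byte-identical clone sequence) guards the bookkeeping.

A transjugant is a background parent carrying: homologous fragments
(intervals whose panel alleles are switched to the donor's), the cassette
replacing the 200 bp mid-section of a target gene with 1000 bp donor-allele
homology flanks (so the cassette integrates by homologous recombination at
its designed locus), optional transposed IS copies, and optional donor-specific genes
implanted at their homologous locus. Fragments are placed only on the
shared backbone — a tract spanning a strain-specific insertion would alter
genome length and is not modelled — with inter-event gaps > 1 kbp and no
internal panel-site gap above the threshold, so each fragment corresponds
to exactly one expected region (a flag disables this to exercise region
merging). Fragment sizes default to log-uniform between a single SNP and
30 kbp, the range observed in the study; the cohort generator draws 1–11
fragments for the chromosome and 0–6 for the megaplasmid, matching the
per-replicon region ranges of the published tables.

Reads are single-end, uniform-start, substitution-error-only, with the
origin (replicon, start) recorded per read. The bundled "naive pileup"
caller piles each read at its recorded origin, takes the majority base per
position (ties broken toward the lexicographically first base), maps the
background backbone through the clone's structural edits, and emits a SNP
wherever a position with depth ≥ 3 disagrees with the background. It
stands in for the external align-and-call step (BWA + GATK in the study),
which is out of scope here: it validates classification and segmentation
under sequencing noise, not read mapping. Paired ends, indel errors,
polyploidy (the organism carries 4–6 genome copies; consensus sequences are
what variant calls describe) and mating kinetics are deliberately not
modelled, so passing tests say nothing about mapping artefacts or
within-cell heterogeneity in real data.

## Default scales and numeric choices

| parameter | default | why |
| --- | --- | --- |
| replicon lengths | 200 kbp + 50 kbp | desk-scale stand-ins for the 1.89 Mbp chromosome + 0.23 Mbp megaplasmid; full size is a config choice, not a code change |
| `snp_density` | 1/124 per bp | the study's genome-wide differential-SNP density |
| specific genes | 12 × 2 kbp + 1 IS per parent (~10% of genome) | matches the study's ~9% non-conserved gene content, which is what recruitment separation rests on |
| `gap_threshold` | 1000 bp | the published "more than 1 kbp" region rule; strict inequality |
| marker flanks / replaced span | 1000 / 200 bp | homology arms of typical cassette constructs; replaced span keeps the target gene annotated |
| `min_query_cover` | 0.40 | the published 40% minimal cover rule |
| `min_identity` | 0.99 (0.95 between parents) | identity stand-in for a zero-e-value match; see Gene capture |
| `max_mismatch_frac` | 0.05 | backbone divergence (0.008) + 1% error with margin, below non-homologous similarity |
| `min_margin` | 5 points | half the smallest observed study margin |
| pileup `min_depth` | 3 | below it a majority vote is meaningless; at 30× coverage P(depth < 3) ≈ 0 |
| validation cohorts | 100 clones (mosaic), 50 clones (capture), 1000 site sets (segmentation) | large enough that a systematic defect cannot hide, small enough to run on one CPU in minutes |

Determinism: every random choice flows from an explicit seed through
`numpy.random.default_rng`; identical seeds give byte-identical FASTA,
FASTQ, VCF, BED, TSV and SVG outputs, and the pipeline manifest records the
config hash and seeds as the reproducibility contract.

## Known limitations

* Region bounds are inner bounds; boundary error is measured against panel
  sites, not against the unobservable true tract ends.
* The alignment-based panel may mis-place sites within ~20 bp of a
  strain-specific insertion junction when gap placement is genuinely
  ambiguous at the sequence level.
* The recruitment matcher is forward-strand, substitution-only; it is not
  a read mapper and must not be used as one on real data.
* Whether published SNP totals include sites inside marker-cassette flanks
  is unknowable from the tables; the simulator counts flank sites as
  implanted (they are genuinely donor-derived), and `evaluate_against_truth`
  scores against that definition.
* Single-SNP regions are assigned no mechanism (gene conversion vs
  artefact); the simulator can generate them (size-1 fragments) but claims
  nothing about their origin.
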