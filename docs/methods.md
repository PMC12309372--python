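# Methods

## Model and procedure

`cdsno` treats C/D box snoRNA detection as window classification followed
by motif-grammar annotation. The unit of prediction is a 194 nt window:
the package admits snoRNAs up to 164 nt and keeps 15 nt of genomic
context on each side, because the terminal stem — a major expression
determinant — forms between nucleotides internal to and flanking the
snoRNA. Scanning enumerates windows at starts 0, *s*, 2*s*, … on both
strands; minus-strand windows keep plus-strand (BED) coordinates and are
classified on the reverse-complemented sequence, so a single coordinate
system runs end to end and GTF conversion (+1, inclusive) happens only in
the writer.

**Merging.** Three ordered filters turn window probabilities into
candidate loci: (i) keep windows with probability ≥ *p1*; (ii) group
maximal runs of positive windows whose starts differ by exactly *s* and
keep runs of ≥ *w* windows; (iii) re-score the run's center window
(lower median for even runs) and keep the run only if that window is
itself positive. Because members already satisfy *p1*, step (iii) is a
no-op in the normal flow; it matters for externally built blocks and for
the optional `--rescue-best-window` mode, which substitutes the
highest-probability member instead of discarding.

**Importance and boxes.** For each retained window the classifier is
interrogated by occlusion: every 6 nt span is replaced by N and the
importance of nucleotide *i* is the base probability minus the mean
probability over all masked variants whose span covers *i* (the 6 nt
span mirrors the k-mer granularity of the per-nucleotide averaging the
approach emulates). The profile is smoothed (Savitzky–Golay, window 11,
order 2) and peaks are local maxima strictly above the profile mean.
Box placement minimizes the summed Hamming distance to the degenerate
consensi (R matches A/G free of charge): C starts in [5, L/2−7], D in
[L/2, L−9], both leaving the 5 nt margin the boundary rule needs. When a
half-window contains peaks, candidate starts must lie within 10 nt of
one — occlusion spreads a motif's signal up to 5 nt downstream and
smoothing can shift an apex by its half-width, so ±6 (one span) proved
too tight in practice. Peak gating is a localization aid only: if the
gated optimum scores worse than the unrestricted optimum the gate is
dropped. Ties are resolved by smaller C score, then C start closest to
the leftmost peak, then leftmost C, then the strongest *implied terminal
stem* (aligned WC+GU complementarity of the 20 nt arms straddling the
implied boundaries), then rightmost D. The stem key earns its place:
CUGA is short enough that exact spurious copies occur every ~256 nt of
background, and internal D' boxes routinely cross the half-window, so
pure positional tie-breaks systematically picked the wrong D; only the
true D is compatible with the stem. The D'–C' pair is then found by
exhaustive search between C and D (absent when the inter-box region is
< 12 nt), and the locus spans from 5 nt upstream of C to 5 nt downstream
of D, mirrored through the window on the minus strand. Loci longer than
164 nt are flagged with a warning but kept.

**Features and refinement.** Five scores feed the refinement step: C and
D Hamming scores, the cumulative score over all four boxes (an absent D'
or C' is charged its maximal score, 4 or 7, to keep candidates
comparable), the terminal-stem score (number of intermolecular pairs ×
duplex MFE of the two 20 nt arms, kcal·nt/mol; each arm is 15 nt of
flank plus the outermost 5 nt of the snoRNA, configurable via
`arm_length`), and the structural score (MFE of the snoRNA divided by
its length, kcal/mol/nt). Folding goes through an engine contract:
ViennaRNA (RNAfold/RNAcofold, DNA read as RNA) when importable,
otherwise the built-in Nussinov engine (max canonical pairs AU/GC/GU,
minimum hairpin loop 3, −1 kcal/mol per pair; `cofold` scores the pure
intermolecular duplex). The subclass classifier returns p(expressed);
the reported confidence is the probability of the predicted class, and
the cascade compares it to *p2* = 0.999. Low-confidence calls pass
through ordered rules — pseudogene if C ≥ 2 and D ≥ 1; expressed if
stem ≤ −25 kcal·nt/mol; pseudogene if fewer than 2 of the 5 features are
favorable; otherwise the classifier's label stands. A high-confidence
pseudogene call is overturned to expressed at ≥ 4 favorable features;
the converse never happens, so the cascade is biased toward the
expressed class by design. Favorable cutoffs default to C ≤ 1, D = 0,
cumulative ≤ 2, stem ≤ −25 kcal·nt/mol, structure ≤ −0.2 kcal/mol/nt.
The cumulative and structural cutoffs correspond to
distribution-derived thresholds that are not printed as text in the
source material; they are explicit `RefineConfig` fields and should be
treated as adjustable defaults.

**Coverage validation.** A prediction passes when same-strand reads
cover ≥ 50% of its length, its mean depth exceeds 5 reads, and *each*
20 nt flank carries at most a third of the locus mean (inclusive bound;
per-flank is the stricter reading of "the flanking regions should not").
Abundance-based labelling calls a snoRNA expressed when any
per-condition mean exceeds 1 TPM.

## Synthetic data: what it emulates and what it does not

The generator implants snoRNA constructs into uniform-random background:
C box 5 nt inside the locus 5' end, D box ending 5 nt inside the 3' end,
D' and C' at random positions in between (≥ 3 nt gaps), and a terminal
stem written as reverse-complementary sequence into the innermost *k*
positions of the two 20 nt boundary arms. Default study conditions:
lengths uniform on 70–140 nt, strands random, half the loci expressed
(perfect boxes, *k* drawn from 8–16 — a constant stem length would be
both unrealistic and degenerate for training), half pseudogenes (2
mutations in C, 1 in D, 2 in each internal box, no planted stem). Loci
sit on an even grid with jitter and ≥ 194 nt of clear background between
constructs. Coverage fixtures give expressed loci uniform depth on their
strand and leave everything else at zero (plus optional Poisson noise).

Dataset construction mirrors the original training protocol: positives
(expressed and pseudogene alike) are snoRNA-centered windows augmented
with five 1 nt shifts per side (10×; the refinement dataset uses 10× for
expressed and 30× for pseudogenes), negatives are shuffled positives and
clean background windows at a 5:1 negative:positive ratio, families with
more than 100 members are randomly capped, and the 10/70/20
tuning/training/test split assigns whole families to single splits
(greedy largest-deficit assignment, ±5 points for divisible group
sizes).

What the generator does **not** emulate: real genomic base composition
and repeats, the six negative classes of the original corpus (tRNA,
H/ACA snoRNA, snRNA, pre-miRNA negatives need external databases),
sequence-level homology within snoRNA families, expression-level
variation, or degraded-but-expressed intermediates. Passing tests
therefore demonstrate that the *pipeline machinery* — scanning, merging,
occlusion-based box localization, boundary and feature computation, the
rule cascade and the coverage filters — behaves exactly as specified on
data with the assumed structure; they say nothing about classifier
performance on real genomes, which depends entirely on the plugged-in
model.

## The reference classifier

The identification and refinement contracts are deterministic maps from
194 nt strings to probabilities. The shipped reference implementation is
a random forest (300 trees, all features per split, fixed seed) over
five box-grammar statistics computed by degenerate motif scans: minimal
Hamming distance to RUGAUGA in the first half-window, to CUGA in the
second half, minimal distances of the internal D' and C' candidates
between them, and the aligned-stem complementarity of the implied
boundaries. Ties among *exact* motif copies are resolved toward the
strongest stem (degraded boxes take deterministic positions so that
grammar-poor windows cannot inflate their stem by maximizing over many
ties), and ambiguous bases count as stem-compatible so that occlusion of
an arm does not masquerade as a box signal. A plain bag-of-6-mers model
was evaluated first and rejected: k-mer counts shared between
independent random genomes reduce to the handful of motif k-mers, which
is far too little signal to reach the extreme *p1* = 0.999 operating
point on unseen sequence. The grammar features are exactly the
invariants the generator plants, so the forest saturates (pure leaves)
on expressed-like windows while background and shuffled windows stay
below threshold. Two consequences worth knowing: pseudogene-like grammar
is close to background noise, so the reference identification model
rarely passes pseudogene loci at default *p1* and occasionally promotes
background windows with coincidentally degraded-looking grammar
(observed precision ~80–100% depending on the genome); and occlusion
profiles are sharp at the one box copy compatible with the stem, which
is what the box-localization step needs.

## Numerical choices and degenerate inputs

Probabilities at filter boundaries are inclusive (≥ *p1*, ≥ *p2*,
stem ≤ −25). Peak detection adds a 10⁻⁹-scale epsilon above the profile
mean so constant profiles yield no peaks despite smoothing ripple.
Sequences shorter than the window warn and yield no windows; windows
with > 10% N are skipped; empty fasta/bedgraph inputs raise format
errors / yield all-zero tracks respectively. Chunked scanning overlaps
chunks by L−1 on the global step grid, so chunk size never changes
results. Even-sized blocks take the lower-median center. `cofold`
returns (0, 0) when no intermolecular pair forms, keeping
0 × MFE = 0 exact. Metric denominators of zero return 0 with a warning.

## Problem sizes

Default test and acceptance runs use 40-locus training genomes (80 kb),
evaluation genomes of 100 kb with 40 implanted loci (20 expressed),
step size 1 scanning on both strands (~200k windows), 500-window box
oracle suites, 200-sequence folding oracles (≤ 14 nt) and 1000-pattern
merging oracles. These sizes were chosen so the whole suite and the
acceptance script each complete in well under a minute on one CPU while
keeping every per-locus behaviour exercised; all of them scale linearly
if larger checks are wanted.

## Known limitations

Boundary recovery depends on the importance profile; duplicate exact
motifs immediately outside the true boxes can still shift a boundary by
more than 3 nt in ~2–5% of loci under the default conditions. The
Nussinov fallback orders stems correctly but its energies are pair
counts, so rule (ii)'s −25 kcal·nt/mol threshold is only meaningful with
a thermodynamic engine. The refinement cumulative/structural cutoffs are
adjustable defaults, not printed constants. Cross-strand duplicate
predictions (same locus called on both strands) are not merged.
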