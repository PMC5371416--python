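# Methods

## The attC site model

An attC site is represented by its top strand (5′→3′, IUPAC alphabet) plus
four box intervals in top-strand coordinates, ordered
R″ < L″ < L′ < R′ and 0-based half-open throughout. The bottom strand — the
strand recombined by the integrase — is the reverse complement; bottom
index of top position *i* is `L − 1 − i`, the single transform used
everywhere. Site sequences are expected to span the full 7-bp R boxes, so
R″ occupies the first and R′ the last seven bases; read on the bottom
strand these are `GTTRRRY` and `RYYYAAC` respectively, and the constrained
("recombinogenic") structure pairs every L′ position against its L″
counterpart plus the four core positions YAAC↔GTTR. The three non-core
R-box positions are left unconstrained: in natural arrays they are not
necessarily complementary between R′ and R″.

Natural site lengths run 57–141 bp; the model treats that range as a soft
bound (a warning, not an error), since the generator and users may build
shorter scaffolds deliberately.

Box location is a best-effort heuristic for well-formed sequences: it
anchors on the terminal R-box consensus (degenerate R/Y codes match their
IUPAC expansions) and scans equal-length L boxes within a bounded spacer
window, scoring `pairable positions − 2 × mismatches` with at most two
mismatches by default, ties broken toward smaller spacers and longer boxes.
Explicit annotations always override it. Sequences without the terminal
anchors raise an "unannotatable" error telling the caller to supply boxes.

**Mismatched stems.** Forcing a non-complementary base pair makes the
constrained ensemble empty. The constraint builder therefore takes a
`mismatch` policy: `error` (default — reject at construction, which
preserves the |L| + 4 pair-count contract), `drop` (omit the
non-complementary L pairs; the cohort pipeline uses this so that imperfect
natural stems still yield a finite pfold), or `keep` (emit them, letting
folding report an empty ensemble and pfold = 0). The choice is surfaced
rather than hidden because it changes what pfold means for imperfect sites.

## Folding thermodynamics

Two energy backends implement one contract (MFE structure + energy,
ensemble free energy, with or without hard constraints):

* **Reference model** — Watson–Crick pairs only, minimum hairpin loop of 3
  unpaired nt, published unified DNA nearest-neighbour stack free energies
  at 37 °C, a flat hairpin-loop initiation penalty (3.0 kcal/mol per
  hairpin loop), no bulge/internal-loop, dangling-end or coaxial terms. The
  open chain has energy exactly 0. The simplification is deliberate: the
  energy of any explicit structure is a short sum, so an exhaustive
  enumeration oracle (≤ 20 nt) can check the dynamic programs term by term.
  The partition function and MFE use O(n³) recurrences over
  `Z(i,j)`/`Zb(i,j)` (and min-plus analogues) with the stack bonus applied
  when the enclosed pair is immediately nested; Boltzmann factors are
  rescaled per nucleotide by `exp(mfe/(n·RT))` so 141-nt sites stay inside
  double range (the log-domain result is recovered at the end). Hard
  constraints enter as masks: a constrained position may not stay unpaired
  and may pair only its designated partner, which makes "every forced pair
  present" a property of all surviving structures. Partner-specific
  forcing (L′ with L″, YAAC with GTTR) was chosen over mere
  "position-is-paired" constraints because the recombinogenic structure
  specifies partner identity.

* **DNA parameter backend** — the ViennaRNA bindings with the DNA
  nearest-neighbour parameter table (`dna_mathews2004`, 1999 set
  selectable), hard constraints applied with the enforce flag, partition
  function after MFE rescaling. This is the backend on the same footing as
  published attC pfold analyses and is the default for pipeline runs.

Temperature defaults to 310.15 K (37 °C) with R = 1.98717×10⁻³
kcal/(mol·K); both are configurable. Reference-model stack energies are
37 °C free energies, so its temperature parameter only enters the
Boltzmann weighting.

pfold is computed as `exp((E_u − E_c)/RT)`, exactly
`Z_constrained / Z_unconstrained`; an empty constrained ensemble maps to
pfold = 0, an empty constraint set gives pfold = 1 identically. Adding a
constraint can only shrink the constrained ensemble, so pfold is
monotonically non-increasing in the constraint set — this is asserted as a
property test, not assumed.

The strand-stability gap is `MFE(bottom) − MFE(top)`; negative values mean
the bottom strand folds more stably. Both constrained and unconstrained
modes are exposed; the unconstrained gap is the default reported by the
pipeline. Note that under the reference model the two strands of a duplex
are exact thermodynamic mirrors (reverse-complement-symmetric stack table,
no loop-sequence terms), so meaningful gaps require the DNA parameter
backend, whose loop, mismatch and wobble terms break the symmetry.

## Replication geometry

The leading strand is defined as the strand with an increasing gradient of
GC disparity (cumulative G−C excess, the Z-curve component). On a circular
replicon the cumulative top-strand profile is detrended (net disparity
spread evenly along the length); oriC is the global minimum, ter the global
maximum. Inference refuses profiles whose detrended amplitude is below
`4·√n` — the range of an unbiased composition's random walk — because the
extrema of a signal-free profile are noise; a user-supplied oriC always
wins (and is the recommended route, mirroring the use of curated oriC
databases).

Strand algebra: where the fork direction is "increasing" (the arc
oriC→ter, rightward with wraparound), the minus strand is the
leading-strand template and the plus strand the lagging-strand template;
the convention reverses on the other replichore, and flipping the strand
always flips the class. This is fixed so that "attC bottom strand on the
lagging-strand template" coincides with the bottom strand being transiently
single-stranded between Okazaki fragments — the mechanistically relevant
case. An integron's orientation is the unanimous per-site class, else the
majority with a `mixed` flag; exact ties are `mixed`.

Consecutive attC sites whose gap is ≤ 4000 bp join one array (15000 bp is
the documented alternative for large sedentary arrays that the default
splits). Cassette length is the start-to-start distance of consecutive
sites (one attC per cassette; end-to-start is exposed as an option),
computed modulo the replicon length when needed. CDS lengths are
partitioned into inside/outside the integron span, with
antibiotic-resistance genes excludable by id.

Classification: an integron is sedentary (SCI) when present in all
sequenced strains of its species or when it has more than 19 attC sites;
mobile (MI) when absent from more than 40% of genomes, on a plasmid, or
when its integrase belongs to one of the five mobile classes. SCI criteria
take precedence; records satisfying both are kept SCI with a conflict
flag; no evidence gives "unknown". Mobile integrons on chromosomes are
reported as MCIs downstream.

## Statistics

Skews are computed on the strand as given (`(G−C)/(G+C)`, `(A−T)/(A+T)`);
zero denominators yield "undefined" (None), never 0. Percent identity uses
global end-to-end alignment (match +1, mismatch −1, gap open −2, extend
−1 — a documented default, since no published scoring accompanies the
reference identity figure) with alignment columns, gaps included, as the
denominator; rounding to an integer happens only at report time. The
rank-sum test enumerates the exact null when the pooled sample is tie-free
and ≤ 12 observations, otherwise uses the tie- and continuity-corrected
normal approximation (scipy); regression is ordinary least squares with a
t-test on the slope (flat responses short-circuit to slope 0, R² 0).
Cohort summaries report the proportion of sites with pfold strictly above
0.1 and inside the closed band [10⁻⁷, 10⁻⁵]; strictness and closure are
documented constants.

## Synthetic data

The generator assembles bottom strands as
`R′ | UCS | spacer | L′ | VTS | L″ | spacer | EHB | R″`, total length
`2·(7 + stem + spacer) + UCS + VTS + EHB`. Unpaired blocks are drawn from
a non-self-pairable alphabet — purines (G/A) for purine-biased bottom
strands, C/A for the reversed bias — so no Watson–Crick pair can form
inside or between them. That serves three purposes: the planted helices
are the only helices (the box heuristic provably recovers clean sites),
the bottom-strand skew is controlled entirely by the unpaired blocks (the
two stem arms cancel each other), and the loop boundaries cannot extend
the planted stem.

Presets: `MI_like` draws 57–74 bp sites with 3–12 nt AT/GA-rich loops,
perfect stems and purine-biased bottom strands (negative top-strand GC and
AT skews); `SCI_vibrio_like` draws 120–129 bp sites with reversed bias
(positive top-strand GC skew, negative AT skew), 1–3 planted stem
mismatches and a *branched decoy VTS*: two segments complementary to L′
and L″ placed inside the loop, so the unconstrained ensemble prefers a
two-hairpin branched fold over the (mismatched) recombinogenic stem and
pfold falls to ~10⁻³–10⁻⁹, part of it inside the 10⁻⁵–10⁻⁷ band seen in
large sedentary arrays. `SCI_other_like` sits between. These emulate the
directions of the published MI/SCI contrasts (pfold, length, skews, gap
sign under the DNA backend); magnitudes are not calibrated to any dataset.

Replicons are built with a G-enriched leading strand on each replichore in
proportion to `skew_strength` (default 0.5, a strong, unambiguous signal),
planted integron arrays whose attC strands realise a requested
leading/lagging-template orientation, one CDS per cassette and longer
background CDSs elsewhere. Everything — boxes, orientations, cassette
lengths — is recorded as ground truth for downstream scoring. What the
generator does *not* emulate: sequence homology between sites of one
array, integrase genes with realistic sequence, EHB identity effects,
replication-associated mutational skews beyond G/C, or any recombination
dynamics. Passing tests therefore demonstrate correctness of the
computations and the stated directional contrasts on controlled input, not
distributional realism of natural genomes.

## Problem sizes and numerical choices

Property tests compare the dynamic programs against exhaustive enumeration
on 200 random sequences of 5–18 nt (relative tolerance 10⁻⁹), the scale at
which enumeration is exact and fast; cohort-level checks use 200 sites per
preset under the reference model; orientation recovery uses 50 replicons
of 24 kb with two arrays each. The acceptance script folds 200-site
cohorts with the DNA parameter backend. Traceback ties in the MFE dynamic
program are broken in a fixed branch order (hairpin, stack, interior;
smallest split point), making dot-brackets deterministic; report files are
byte-identical across runs with the same configuration and seed.

## Known limitations

* No pseudoknots, multistrand complexes, kinetics, or supercoiling-driven
  cruciform extrusion energetics; pfold is an equilibrium single-strand
  quantity.
* The reference model's strand symmetry (above) makes it unsuitable for
  strand-stability gaps; use the DNA backend.
* The published fold probabilities of the excision-assay sites can only be
  checked once their supplementary sequences are supplied
  (`data/reference_attc_bottom_strands.fasta`); the repository does not
  redistribute them, and the corresponding tests fail with an explanatory
  message until the file is present.
* Dataset-scale genomic results (hundreds of integrons across RefSeq
  genomes) require the original annotation tables and genome sequences;
  the pipeline ingests those formats, but no genomic claims are recomputed
  here.
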