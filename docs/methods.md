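# Methods

This note documents the models, conventions and numerical choices behind
`mepsurvey`, and what the synthetic benchmarks do and do not demonstrate.

## ORF model

ORFs are extracted by direct six-frame scanning: both strands of each
contig, three frames per strand. An ORF runs from a start codon to the
first in-frame stop codon, inclusive; its nucleotide length therefore
includes the stop, so the default 150 nt minimum corresponds to a ≥ 49 aa
peptide plus stop. Conventions, chosen for determinism and documented
because ORF callers differ on them:

* **Start codons**: ATG only by default (`start_codons` is extensible to
  GTG/TTG). The synthetic generator plants ATG-initiated genes, so the
  benchmark is self-consistent under this choice.
* **Nested starts**: only the 5′-most qualifying start per (frame, stop)
  is reported — one ORF per stop codon, avoiding duplicate peptides
  hitting the same profile.
* **Run-off ORFs**: an open frame reaching the contig end without a stop
  is reported if long enough and flagged `has_stop=False` (tolerance for
  draft assemblies).
* **Coordinates**: 0-based half-open on the forward strand, so reverse
  complementation mirrors intervals exactly.
* **Ambiguity**: IUPAC codes other than N are collapsed to N on input;
  codons containing N translate to X and never act as start or stop.

Translation tables 1 and 4 are supported; table 4 (TGA = Trp) is assigned
automatically to the genera *Spiroplasma*, *Mycoplasma*, *Mycoplasmoides*,
*Malacoplasma* and *Ureaplasma*, with an explicit override available.

## Profile HMM

One profile per gene-role family, estimated from the family alignment:

* **Match states**: alignment columns with ≤ 50% gaps (a standard
  profile-construction heuristic).
* **Emissions**: `(count + α)/(total + 20α)` with pseudocount α = 0.1 by
  default. Small families (the seven-member DxrII-style case) need the
  smoothing; α is exposed in the API.
* **Transitions**: the seven Plan7-style probabilities (M→M/I/D, I→M/I,
  D→M/D) plus begin→M/D, estimated from observed column-to-column paths
  with the same pseudocount. Insert runs adjacent to deletions have no
  legal path in this topology (no I↔D transitions) and are dropped from
  the counts.
* **Background**: uniform 1/20 by default, overridable with empirical
  frequencies. Insert states emit the background, so inserted residues
  cost only their transitions.

**Scoring** is best-path (Viterbi) in bits: log2 of the best state-path
probability over the background probability of the emitted residues. The
alignment is global in the model and local in the sequence: the begin and
end states are reachable at every sequence position at no cost, so
flanking residues contribute zero bits. X residues emit at the background
rate (log-odds 0). The empty peptide scores the all-delete path. This
statistic is deliberately simpler than HMMER's forward/glocal score —
absolute bit scores will **not** match HMMER's — but every threshold in
the package is calibrated on the same statistic, so presence/absence
calls are internally consistent. The dynamic program is verified against
exhaustive path enumeration on all tiny models (M ≤ 4, peptides ≤ 6) in
the test suite, and the kernel is JIT-compiled with numba (a pure-Python
fallback of the same function runs if numba is unavailable).

**E-values** use a Gumbel (extreme-value) null fitted by maximum
likelihood (`scipy.stats.gumbel_r.fit`) to the scores of ≥ 100 random
background peptides of model length:
`E(s) = Z · (1 − exp(−exp(−λ(s − μ))))`. The database size `Z` is bound
at scan time to the number of ORFs searched in the genome at hand,
mirroring the search-space semantics of an e-value. Calibration fails
loudly on degenerate (zero-variance) score distributions.

## Adaptive thresholds

Per family, the curated positives are shuffled (seeded) and split into
three groups with sizes differing by at most one. Each of three rotations
builds a profile from two groups and scores the held-out group plus all
negatives; the candidate thresholds are the midpoints between adjacent
distinct pooled scores, plus one candidate below the minimum and one above
the maximum (offset by the score range, so the scan commutes with affine
rescaling). The candidate maximizing F = 2PR/(P+R) is kept, ties broken
toward the higher threshold; `score ≥ threshold` calls an ortholog (the
midpoint grid makes the boundary convention immaterial except at exact
ties, where the shared value is classified positive). The family threshold
is the mean of the three fold thresholds and the reported F is the mean of
the fold F values — both per-fold and averaged numbers are kept, rather
than re-evaluating F at the averaged threshold. Fewer than three positives
is an error directing the caller to e-value mode; the e-value-mode roles
(DxrII, IspD, IspF) use a 1e-10 cutoff. The midpoint scan is exact for the
step-function F, so no grid resolution parameter exists.

`adaptive_threshold` takes unaligned, equal-length positives (the trivial
columnwise alignment); families with indels should be aligned upstream and
passed to `build_profile` directly.

## Classification and census

MEP completeness is evaluated over seven role slots, with DxrI/DxrII
interchangeable in the Dxr slot and the IspDF fusion satisfying both the
IspD and IspF slots; only domain presence matters, not whether a protein
is mono- or bifunctional. MVA presence requires ≥ 2 of 4 slots (the HMGR
isoforms count once). The five genotype classes partition all presence
rows; the boundary between `neither` (zero MEP slots, ≤ 1 MVA gene) and
`candidate` (1–6 MEP slots, ≤ 1 MVA gene) is fixed here explicitly, and
`MVA_only` takes precedence over `candidate` when the MVA pathway is
present. The partition is verified exhaustively over all 2^14 relevant
rows against an independently coded rule oracle.

Census percentages follow the survey reporting convention: shares < 10%
round (half up) to one decimal, others to the nearest integer; raw
fractions are always carried alongside. The MTA-shunt fractions use the
Dxs-only candidates as denominator. A genus is *bifurcated* when it has
≥ 2 species, at least one on the MEP side (`MEP_only` or `both`, whose
MEP set is complete by construction) and at least one `MVA_only` species.
Medians over even-sized sets are the mean of the central pair.

## Synthetic data: what it emulates, and what it does not

Families are i.i.d. per-site substitution processes around a background-
sampled ancestor (uniform choice among the 19 alternative residues), with
no indels by default so the alignment is trivially correct and profile
tests isolate scoring behaviour; a per-site deletion rate is available
behind a flag. Expected pairwise member identity is (1−d)² + d²/19 at
divergence d, which the tests check in closed form. Negatives are
shuffled members (same composition, destroyed positional signal) plus
length-matched background peptides.

Genomes are gene cassettes (uniform synonymous reverse translation under
the genome's table, ATG-prefixed, stop-suffixed) planted on random strands
between stop-rich spacers built from the codon tokens TAA/TAG/CTA/TTA —
stops on the forward strand and reverse complements of stops — with rare
phase-shift nucleotides, so intergenic sequence cannot host a ≥ 150 nt
ORF and contains no ATG. Decoy genes encoding unrelated random peptides
are planted alongside. Every planted cassette is asserted to translate
back to its peptide at generation time. Default study conditions: 300 aa
ancestors, 30 members per family, 2 decoys per genome, 60 bp mean
intergenic length; full-pipeline benchmarks use a 440-genome cohort with
genotype composition 341/54/8/14/23 at 5% divergence (exact composition
recovery) and a 30-genome cohort at 10% divergence (recall/false-presence
measurement). These sizes keep the complete benchmark suite to a few
minutes on one CPU while exercising every stage at realistic protein
lengths.

What passing these benchmarks does **not** show: real protein families
have site-specific rate variation, indels, paralogs, and shared ancestry
between families (IspD/IspF/IspDF really are homologous domains, unlike
the independent synthetic families), and real intergenic DNA contains
spurious ORFs and pseudogenes. The synthetic results validate the
machinery — scoring, calibration, calling, classification, census
arithmetic — not the biological recall of any particular family model on
real genomes. Reproducing a published survey's exact presence/absence
calls would additionally require that survey's curated families and the
scoring statistic of the original search tool.

## Numerical and degenerate-case choices

* Log-space DP with −1e300 as the impossible-path sentinel; zero
  transition probabilities are representable.
* `f_measure(tp=0, ·, ·) = 0` resolves the 0/0 precision–recall corner.
* Empty peptides score the all-delete path; empty cohorts, empty
  matrices and header-only TSVs round-trip losslessly.
* All randomness flows through `numpy.random.default_rng` from explicit
  integer seeds; identical seeds give byte-identical generated FASTA and
  scan detail TSVs.
* TSV outputs are tab-separated, UTF-8, Unix newlines, no quoting, for
  bit-exact diffing.
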