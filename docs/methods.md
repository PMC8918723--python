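# Methods

## Model and pipeline

metharc analyses directional (non-PBAT) methylation sequencing
libraries. The chemistry acts on single strands: in WGBS, bisulfite
deaminates unmethylated C to U (read as T) leaving 5mC intact; in TAPS,
TET oxidation plus pyridine borane reduction converts 5mC to DHU (read
as T) leaving unmethylated C intact. R1 reads the chemistry-converted
strand 5'→3'; R2 reads its complement, so in genome space R1 carries C/T
signal and R2 carries G/A signal.

The reference is transformed into a *pseudo-genome*: for every
chromosome, a converted Watson sequence (kept under the original name)
and a converted Crick sequence (reverse complement, named
`<chrom>#rev` — `#` cannot occur in conventional chromosome names, so
back-mapping is unambiguous). Conversion is either 3-letter (all C→T) or
4-letter (C→T only when the next base is G). Reads are converted with
the mate-specific analogues (R1 C→T, R2 G→A; CpG-restricted versions in
4-letter mode) and aligned once. Because both strands are present in the
index, a legitimate converted read always matches some pseudo-chromosome
in *forward* orientation (as read 1 of the fragment); for single-end
data, reverse-orientation hits are chemically impossible artifacts and
the builtin aligner never searches them — this is precisely how the
single-pass design assigns the bisulfite strand.

Restoration: a hit on a Watson-origin pseudo-chromosome keeps its
position and CIGAR (strand OT); a hit at `pseudo_pos` on a Crick-origin
pseudo-chromosome of length `L` maps to
`pos = L − pseudo_pos − reference_span(cigar)` with the CIGAR reversed
element-wise and the orientation flipped (strand OB). Reported sequences
are always the original (unconverted) bases in Watson orientation, so
downstream calling reads methylation directly from the BAM.

## Builtin aligner

The builtin aligner is a deterministic exact-seed, ungapped-extension
aligner intended for moderate genome sizes: 16-mer seeds from the read
start at stride 4, candidate loci scored by mismatch count with a budget
of ⌈0.04·read length⌉, seeds hitting more than 256 index positions
skipped. Paired ends must land on one pseudo-chromosome in FR
orientation within 1000 bp. Ties for best score are ambiguous: by
default the pair is reported unmapped (`--random-tie` resolves ties with
a per-read seeded RNG instead). MAPQ is a convention, not a probability:
42 for unique hits, 0 for ambiguous ones. Indel-containing CIGARs are
fully supported by the restoration and calling layers and enter via the
external-aligner adapter (Bowtie2/Hisat2 over the pseudo-genome FASTA)
or synthetic fixtures; the builtin aligner itself is ungapped by design.

## Trimming

Per mate: (1) 3' adapter search — adapter prefix matched at every read
suffix, 8 nt exact seed, ≤10% mismatches over the overlap, minimum
overlap 3 nt, leftmost hit wins (defaults: Illumina TruSeq adapters);
(2) 3' quality trimming by the BWA-style running-sum rule at Q20;
(3) head/tail clipping of exactly the configured cycle counts — applied
*after* adapter/quality trimming because it targets end-repair artifacts
of the insert itself; (4) pairs with either mate shorter than 36 bp are
dropped whole (no singleton rescue). Head-clip offsets are carried into
the BAM (`XH:i`) so M-bias can place observations on original
sequencing cycles.

## Duplicate removal and calling

Duplicates share (chrom, fragment start, fragment end, strand) for
paired data, (chrom, pos, strand) for single-end; the copy with the
highest summed base quality is kept (tie: first in coordinate order).
MAPQ < 20 alignments are counted separately ("low-quality") before
deduplication, mirroring the report's separate accounting of low-quality
alignments, duplicates and reported fragments.

Calling walks aligned bases at indexed CpG sites: OT fragments are read
at the Watson C (C = retained, T = converted), OB fragments at the
Watson G, i.e. the Crick C (G/A). Retained means methylated under
bisulfite and unmethylated under TAPS — swapping the chemistry flag on
identical input exactly swaps the counts. Bases under Q20 or outside
{C,T}/{G,A} are skipped. Overlapping mates contribute at most one
observation per site (higher base quality wins, tie → mate 1). Outputs
carry strand-resolved and merged counts; β is printed to 4 decimals in
text outputs and at full precision in machine-readable ones.

The spike-in conversion rate uses *all* cytosines of the designated
spike-in chromosomes (default name `lambda`, set explicitly on the CLI —
the headline rate is all-context, with a CpG/non-CpG breakdown also
reported): it is the fraction of observations behaving as the chemistry
predicts for unmethylated input (converted under bisulfite, retained
under TAPS). Zero informative coverage yields a flagged "not estimable"
result rather than a number.

## Simulator

The simulator defines the study conditions for all tests: uniform ACGT
genomes (default 100 kb) overlaid with one 400 bp pyrimidine- or
purine-skewed block (base probabilities 0.4/0.4/0.1/0.1) per ~8 kb,
emulating the CT-rich stretches around regulatory elements while keeping
GC at 0.5 in expectation; an optional 5 kb fully unmethylated
lambda-like spike-in receiving ~10% of fragments; per-CpG truth betas
from a bimodal Beta mixture (70% Beta(8,2), 30% Beta(2,8)) resembling a
somatic methylome, or a constant; fragment lengths Normal(167, 30)
truncated at 30 bp; 100 bp paired reads with adapter read-through on
short fragments; conversion rate 0.995 for the chemistry's target
cytosines and 0.005 inverse failure; substitution errors at 0.001
(no indel errors); non-CpG cytosines fully unmethylated
(mammalian-like). Read IDs encode the true fragment
(`r<i>:chrom:start:end:strand`), the interchange contract used by the
mapping-accuracy evaluator. An optional switch forces unmethylated calls
at the first read-2 cycles to emulate the end-repair overhang artifact
seen in real libraries.

What the simulator does **not** model: instrument-specific quality
profiles, indel sequencing errors, CNVs/repeats beyond the skewed
blocks, hemimethylation (both strands of a molecule are drawn from one
template), or chimeric fragments. Passing tests therefore demonstrate
correctness of the algorithms under idealised-but-noisy conditions, not
performance on pathological real-genome repeat structure.

## Numerical and design choices

- Coordinates are 0-based half-open internally and in call TSVs; SAM/BAM
  output is 1-based per the format; CpG call rows span the CG
  dinucleotide (start, start+2) when strand-merged.
- A C before N or at a sequence end is *not* CpG context in 4-letter
  mode (conservative; the mismatch budget absorbs the rare edge).
- N runs in the reference are retained verbatim in the pseudo-genome;
  seeds containing N are skipped.
- Determinism: outputs are byte-identical for a fixed seed and config at
  any `--threads` setting. Reads are processed serially in input order;
  the thread count is forwarded only to an external aligner. Gzip
  streams are written with mtime 0, BAMs are sorted in-process with a
  total order (tid, pos, name, flag), the BAM header carries no
  timestamp, and matplotlib SVGs use a pinned hash salt with no creation
  date.
- Test problem sizes (100 kb genomes, ≤10k fragments, ~50× depth) were
  chosen so the whole suite exercises every stage at statistically
  informative depth while remaining desk-scale; thresholds (≥99%
  efficiency, exact-locus accuracy, 99% binomial CIs with ≥95% coverage,
  3 SE on the conversion rate) follow directly from the binomial
  sampling model of the simulator.

## Known limitations

The builtin aligner is ungapped and unsuitable for mammalian-scale
genomes (use the Bowtie2/Hisat2 adapter there); only directional
libraries are supported; CHG/CHH methylation is not called (non-CpG
cytosines are used solely for conversion-rate estimation); the HTML
report is static.
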