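# Methods

This note records the models behind `dualstore`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and
the design choices made where the physical system leaves the software
design open.

## Strand codec

### Layout and constants

All structure lives in `SequenceLayout` (defaults in parentheses):
two modulation primers (4 nt each), index (4 nt = 8 bits, so ≤ 256
strands per file), payload (100 nt = 25 bytes), inner Reed–Solomon
region (8 nt = 2 bytes), seed (4–16 nt in 4-nt steps), PCR primers
(20 nt × 2), outer RS region (8 nt). The regions tile the 124-nt
minimum core exactly: 4+4+4+100+8+4 = 124. Files are framed with a
2-byte little-endian length prefix and zero-padded into 25-byte
chunks, one strand per chunk with consecutive indices; capacity is
256·25 − 2 = 6,398 bytes per primer pair.

Constraint thresholds — GC fraction in [0.40, 0.60], homopolymer runs
≤ 3 — are the community-standard synthesis/sequencing compatibility
window; the physical system they model states the criteria but not the
numbers.

### Modulation

Modulation is a cyclic keystream addition mod 4 (bases as integers via
A=0, C=1, G=2, T=3): `out[i] = seq[i] + primer[i mod 4] (mod 4)`. It
is length-preserving, invertible by subtraction, and composes as a
group action (modulating by p then q equals modulating once by p+q).
The physical coding scheme only states that modulation "maps the
sequence onto alternative sequences"; the Vigenère form is the minimal
operation with those properties. The screening loop tries an ordered
pool of all 96 constraint-compliant 4-nt words for both primer slots,
then seed paddings of growing length (up to 4 random draws per
length, drawn from the same compliant-word pool), and accepts the
first core that passes the constraints — reproducibility is preferred
over rate optimality. Encoding is deterministic: the per-chunk RNG is
seeded with (file seed, file id, index).

### Error correction

Both RS layers work over GF(256) with polynomial 0x11D and 2 parity
bytes (= 8 nt at 2 bits/nt), correcting 1 byte each. A GF(4) code
could not span these block lengths, and 8 nt of parity is exactly 2
field symbols. The inner code protects index ‖ payload ‖ the two
modulation-primer identifiers (28 bytes); the outer code protects the
whole core (≤ 34 bytes). The decoder chain is syndromes →
Berlekamp–Massey → Chien search → a direct Vandermonde solve for the
error magnitudes, with a final syndrome re-check so that uncorrectable
words raise instead of mis-decoding. Note the information-theoretic
limit: with distance 3, about 10 % of two-error patterns land within
distance 1 of a *different* codeword and are necessarily mis-corrected
by any bounded-distance decoder; the tests pin the implementation to a
brute-force nearest-codeword oracle rather than pretending otherwise.

### Region order

The deliverable strand is `fwd ‖ core ‖ RS_outer ‖ revcomp(rev)`. The
order of the two appended elements is not fixed by the physical
description ("finally appended"); placing the primers at the extreme
ends keeps them usable as two-end anchors for read filtering.

## Bitmap codec

Concise text is UTF-8 behind a 32-bit big-endian byte-length header,
bits packed MSB-first, row-major from the top-left, zero-padded to the
smallest square. A header beats sentinel padding because flipped
padding bits then cannot corrupt the payload. Catalog records
serialize one `id|name|row|col` line per unit; concise files append a
`PRIMERS|fwd|rev` trailer line, with backslash escaping so arbitrary
bodies round-trip. No error-correcting code is applied to bitmaps (the
physical read-out is demonstrated error-free at these array sizes).

## AFM imaging channel

Dots are Gaussian protrusions with σ = FWHM/2.355; defaults FWHM
50 nm, height 10 nm, pitch 100 nm, pixel size 5 nm/px (a dot spans
~10 px), background tilt (0, 0) nm/px and iid Gaussian height noise
(1 nm sd). A Gaussian is the minimal parametric shape consistent with
a protrusion characterized only by FWHM and height; tip convolution,
drift and creep are not modeled.

Decoding: (1) least-squares plane flattening in two passes — global
fit, then refit on the lower residual half so the dots do not bias the
background; (2) grid detection from row/column projections of the
positive part: peak positions (prominence ≥ 0.3 of the dynamic range)
give candidate lattice lines, spacings are reconciled as near-integer
multiples of a common pitch (so rows/columns that happen to carry no
dots are tolerated), and irregular spacings raise an error rather than
guessing; (3) per-site binarization: a cell is 1 iff the maximum
height in a (pitch/2)-radius window exceeds 50 % of the robust dot
amplitude (median of site maxima above a floor of 5 background MADs).
Thresholding at half amplitude after flattening mirrors "adjusting the
color contrast" without reverse-engineering vendor software.

When bitmaps are written through this channel by the library layer, a
fiducial border of 1-dots frames the array. The payload's first row is
the length header's leading zeros, so the physical array would
otherwise begin with an undetectable empty row; a border is the
standard lithographic answer and is stripped after read-out.

## Sequencing channel

Reads per strand are Poisson(coverage), default 100×, modeling library
sampling. Each read passes through iid per-base substitution /
insertion / deletion edits (defaults 3 % / 2 % / 3 %, nanopore-like
magnitudes; substitutions always change the base) and is
reverse-complemented with probability 0.5 — amplification releases the
complementary strand, so the decoder must be orientation-blind.
Homopolymer-conditional error spectra, chimeras and quality scores are
not modeled; passing tests therefore show robustness to iid edit noise
at realistic rates, not to instrument-specific artifacts.

## Read decoding

1. **Filter/trim**: each read (both orientations) must show the
   forward primer within the first 32 nt and the reverse-complemented
   reverse primer within the last 32 nt, each within 4 edits
   (semi-global alignment; ~98 % of channel reads pass, and reads from
   a different file's primer pair — designed at mutual edit distance
   ≥ 8 — are rejected). Trimmed interiors must lie within ±12 nt of
   the expected span.
2. **Clustering**: abundance-greedy sphere clustering — unique reads
   sorted by multiplicity (lexicographic tiebreak), the most abundant
   unassigned read seeds a cluster and absorbs everything within a
   fixed Levenshtein radius. `cluster_reads` defaults to radius 3; the
   recovery pipeline clusters at radius ≈ interior/4 (33 nt for the
   default layout) because two same-strand reads at ~8 % per-base
   error typically differ by ~21 edits while unrelated payloads differ
   by ~65 — a tight radius would shatter every true cluster into
   singletons. Message-passing refinement (as in trie-based sphere
   clustering tools) is deliberately omitted.
3. **Selection**: the top n clusters by abundance, n supplied by the
   library manifest; ties at the boundary break lexicographically.
4. **Consensus**: selected clusters are polished by alignment voting —
   members are globally aligned to the draft, each draft position
   takes the majority base-or-deletion, and an insertion is applied at
   a gap when a majority of members insert *something* there (the
   plurality string wins; thresholding per exact string instead would
   split votes whenever alignment ambiguity in repeats shifts the
   insertion point). Up to two rounds, re-drafting between rounds.
   Consensus is essential for byte-exact recovery: at 8 % per-base
   error on ~132-nt interiors the probability that any single read is
   error-free is ~e⁻¹¹, so selecting raw cluster representatives
   cannot reproduce the original strands; voting across ~100 reads
   with independent errors can, and residual errors fall to the RS
   layers. The selection-only path is retained:
   `evaluate_against_originals` measures the edit-distance error rate
   of the raw selected chains against the true strands (by decoded
   index when available, else minimum-cost assignment; unmatched
   originals count their full length), the metric the physical
   demonstration reports as nonzero error bars.
5. **Decode**: outer RS → fixed-offset parsing → demodulation → inner
   RS → chunk reassembly by index. Missing chunks are zero-filled and
   flagged in the per-strand status rather than raising.

The report's `error_rate` is the residual edit distance between each
decoded input sequence and its RS-corrected reconstruction (failed
decodes count full length) — 0.0 exactly when consensus removed every
channel error.

## Aging and repeated access

Thermal decay is first order: k = exp(lnA − Ea/RT), each copy
surviving an interval t independently with probability exp(−kt).
First order is the standard kinetics for DNA strand scission and the
only order with a well-defined half-life. Default synthetic-aging
parameters Ea = 97.81 kJ/mol and lnA = 39.01 /yr emulate
surface-immobilized DNA: the activation energy sits below free DNA's
120–155 kJ/mol (strands can also break at the anchoring bond) and the
pair yields a 40-year half-life at 0 °C. The generator samples one
half-life at 60/70/80 °C with 10⁵ copies per point; fitting ln k
against 1/T recovers Ea within 3 % at these sizes.

Repeated access: `in_situ` templates are surface-bound and copied
without consumption — trajectories are exactly constant. `pooled`
access removes Binomial(count, consumed_frac) templates per access
(default 1 %), then re-amplifies with per-strand efficiencies drawn
once from Normal(0.9, 0.05) truncated to [0, 1] and applied over 10
cycles, renormalized to the initial pool size: per-strand efficiency
is a sequence property, so bias compounds and the coefficient of
variation of relative abundances grows with every access. The physical
description quantifies neither the consumed fraction nor the
efficiency spread; both are free parameters with these documented
defaults.

## Density analytics

ρ = d⁻² (nanodots) and ρ = L·d⁻² (DNA), evaluated as ρ = (10⁶/d_nm)²
bit mm⁻². With L = 248 bits (124 nt at 2 bits/nt): 4×10⁸ bit mm⁻² at
d = 50 nm, 10¹⁰ at 10 nm, 2.48×10¹² for DNA at 10 nm and 2.76×10¹³ at
3 nm.

## Demo library and problem sizes

The demo library holds a catalog plus five units (seal, name, motto,
anthem, ethos) on a 2×3 logical grid, with payloads of 1,595 (binary),
404, 260, 620 and 180 bytes — the first two match the demonstrated
payload sizes; contents are deterministic pseudo-random text/bytes
under the library seed, since the original files are not
machine-readable. All primer pairs are mutually orthogonal (pairwise
edit distance ≥ 8 across the whole set). The shipped tests and the
acceptance script run at these sizes — the 1,999-byte fixture
(81 strands, ~8,100 reads at 100×) and 28×28 dot arrays — which a
single workstation core handles in seconds per run while exercising
every pipeline stage at full coverage.

## Known limitations

* The overall coding rate of this layout (25 bytes per ~172-nt strand,
  ≈ 1.16 bit/nt) is a design choice of this implementation; the
  physical system's unpublished modulation tables imply a different
  rate, and its exact strand count for a given payload is therefore
  not reproduced (81 strands here for 1,999 bytes).
* The iid error channel and Gaussian dot model are deliberately
  minimal; conclusions about real instruments require their error
  spectra.
* Sphere clustering is exact greedy (verified against a brute-force
  oracle) but O(centroids × unique reads); it is sized for
  per-file access (≤ ~10⁴ reads), not pooled whole-library sequencing.
* The aging analysis assumes survival fractions are observable
  directly; mapping from qPCR copy numbers or sequencing-intact
  fractions to survival is outside scope.
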