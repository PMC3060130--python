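# Methods

This note records the models, numerical choices and deliberate dialect
decisions behind `cytostd`, and what the synthetic data do and do not
establish.

## FCS reading and writing

The written dialect is FCS 3.1, single dataset per file, delimiter
`/` (0x2F), UTF-8 TEXT.  Reading accepts 2.0/3.0/3.1 headers liberally
(the version tag only routes keyword expectations), follows `$NEXTDATA`
chains through an explicit `dataset_index` argument, and falls back to
Latin-1 with a warning when TEXT is not valid UTF-8.  `$DATATYPE` F, D
and I are supported; ASCII (A) is deprecated in 3.1 and rejected with a
named error.  Integer data are masked per parameter to the next power
of two above `$PnR` minus one, as the standard requires; mixed-width
integer rows use a numpy structured dtype, so decoding stays
vectorized.  On write, `$BEGINDATA`/`$ENDDATA` are always present in
TEXT (3.1 requires them) and the 58-byte header carries the same
offsets unless they exceed the 8-digit field, in which case the header
fields are zeroed and TEXT is authoritative.  TEXT length depends on
the offset digits, so the writer iterates to a fixed point (converges
in ≤ 2 passes in practice, with an 8-pass guard).  The delimiter-escape
grammar (doubling) cannot unambiguously represent keys or values that
begin or end with the delimiter; the writer rejects those, and the
reader uses the greedy left-to-right scan that the doubling convention
implies.  The trailing CRC field is written as `00000000` (not
computed) and not verified on read.

## Scale transforms

The five transform kinds use the harmonized (T, M, W, A)
parameterization: T the top-of-scale data value (f(T) = 1 for every
kind), M decades, W linearization width in decades, A extra negative
decades (or the linear offset for `flin`).  Closed forms:
flin(x) = (x+A)/(T+A); flog(x) = (1/M)·log10(x/T) + 1;
fasinh(x) = (asinh(x·sinh(M ln10)/T) + A ln10)/((M+A) ln10).  The
logicle is the inverse of the biexponential
B(y) = a·e^{by} − c·e^{−dy} − f reflected about y = x1 for the negative
range, with b = (M+A) ln10 and d the root of
2 ln(d/b) + w(b+d) = 0, w = W/(M+A) (solved by Brent to 1e-14; d = b
exactly when W = 0); hyperlog is the inverse of the strictly increasing
EH(y) = a·e^{by} + c·y − f.  Constants are cached per transform
instance.  Forward logicle/hyperlog values are obtained by vectorized
bisection on the closed-form inverse: a bracket-growing phase (64
doublings for extreme inputs) followed by 120 halvings, leaving
residuals far below the 1e-12 top-of-scale and 1e-9 round-trip
tolerances the tests assert.  Display values outside [0, 1] are
extrapolated rather than rejected, since the underlying functions are
defined there.  `flog` of non-positive data yields NaN with a warning
(vectorized use), not an exception.

## Compensation

Convention, fixed and worth stating twice: with events as row vectors,
observed = true·S, so compensation right-multiplies by S⁻¹.  Rows of S
are fluorochromes, columns detectors — the `$SPILLOVER` orientation.
Matrices parsed with non-unit diagonals are normalized by their
diagonal with a warning.  Near-singularity (|det| < 1e-12 at the
matrix's scale) raises a numerical error naming the condition number
instead of returning garbage.

## Gate semantics

Boundary rules are pinned because consistency matters more than the
choice: rectangles are min-edge inclusive / max-edge exclusive;
polygon and ellipsoid boundaries are inclusive.  Polygons use even-odd
(crossing-number) membership, so self-intersecting polygons are legal
and get the even-odd interpretation; zero-area polygons are rejected at
construction.  A gate's population is its own predicate AND its
parent's, recursively; Boolean gates reference other gates' full
memberships (including those gates' parents), with optional per-operand
complement.  Reference cycles are reported with the cycle path.
Rectangle gates are evaluated in data space by inverse-transforming
their bounds (valid because every transform is strictly increasing);
polygons and ellipsoids are evaluated in display space.  Both paths are
exercised against each other for rectangles in the tests.  Quadrant
gates, decision trees and curly quadrants are recognized and rejected
by name.  The XML dialect follows the Gating-ML element shapes
(namespaced gates, `fcs-dimension` channels, `transformation` and
`spectrumMatrix` registries); reading is namespace-tolerant across the
published gating namespaces where shapes coincide, writing pins the
v2.0 URIs.

## CLR dialect

CSV with one header row of class labels, one row per event in the
source file's event order, no index column, optional leading
`#source=<name>` comment.  Values are serialized with `repr` (shortest
round-tripping decimal, ≤ 17 significant digits) so round-trips are
bit-exact.  Row sums ≤ 1 is an opt-in *strict* check — fuzzy and
overlapping classes are legal by design, so permissive is the default.
Hard assignment takes the argmax when it reaches the threshold, with
first-label tie-breaking by default (an `unclassified` tie rule is
available).

## ACS dialect

The table of contents is `TOC.xml` at the archive root (any root member
matching `TOC*.xml` is accepted on read) under a pinned namespace with
a `version` attribute.  Integrity is per-entry SHA-256 checksums;
opaque `signature` elements round-trip byte-for-byte as the extension
point for real digital signatures, which are out of scope.  The
relationship vocabulary (preprocessed-from, gating-description-of,
classification-results-of, compensated-version-of, derived-from) is
open: unknown terms warn rather than fail.  Validation returns findings
(level, code, message) instead of raising, and is complete over the
four structural mutation classes (member removed, entry removed, byte
corrupted, relation dangled) — asserted by test.  Archives are written
with zeroed timestamps, fixed member order and deflate compression
(stored above 64 MiB per member, where decompression time dominates),
so equal containers pack to equal bytes.

## Synthetic PBMC panel

The generator emulates a 10-channel stimulated-PBMC panel: scatter
(FSC-A, SSC-A), surface markers (CD123, CD11c, MHC-II, CD14), cytokines
(IL-6, IL-12, TNF-a, IFN-a).  Events are drawn from a Gaussian mixture
on a log10 latent scale and exponentiated, giving log-normal
population clouds; the configured spillover (6% adjacent-detector, 1.5%
second-neighbour crosstalk) is applied to the fluorescence channels,
and values are clipped to [0, $PnR).  Populations and defaults
(weights: monocytes 0.28, B cells 0.25, debris/dead 0.15, mDC 0.10,
novel-1 0.08, pDC 0.07, novel-2 0.07; scatter σ 0.06 and marker σ 0.15
decades; 20,000 events per sample) live in
`src/cytostd/data/populations.yaml`.  They were chosen once to realize
the qualitative marker logic used in PBMC immunophenotyping — monocytes
CD14-high, pDC CD123-high, mDC CD11c-high, B cells
MHC-II-high/CD14-low, debris low-scatter — with ≥ 3σ separation between
each population and the gate boundaries that select it, so the fixed
gates recover ≥ 95% of their populations by construction.  Cytokine
channels are bimodal (responder fractions 0.35–0.45) inside the
antigen-presenting populations to emulate stimulation.  What this does
**not** model: real LSR II intensity distributions, autofluorescence,
doublets, time drift, or genuinely overlapping populations.  Passing
tests therefore demonstrate the correctness of the format and
evaluation machinery under clean, separable conditions — not clustering
performance on real cytometry data.

## Example pipeline

Preprocessing removes events outside the live-cell scatter rectangle,
compensates with the file's own `$SPILLOVER`, and subsets to
scatter + surface markers.  "Manual" gating is the fixed hierarchy
(live → monocytes; live → CD14-low → pDC ellipsoid / mDC polygon /
B-cell rectangle) stored as Gating-ML, with marker dimensions on a
shared fasinh display scale (T = 262144, M = 4.5, A = 0).  The
automated stage is Gaussian-mixture EM (full covariances, k = 6 by
default, k-means++ initialization, 5 restarts, reg_covar 1e-6) on the
transformed surface markers; posterior responsibilities become the
fuzzy CLR table.  Clusters are matched to gated populations by
maximum-weight Hungarian assignment on the hard-label contingency
table; unmatched clusters are labelled "novel".  Comparison reports
per-population precision, recall and F = 2PR/(P+R) (0 when P+R = 0).
The example container bundles two samples (child seeds spawned from the
user seed via `SeedSequence`), and records per-sample gate counts in
the ToC so `example verify` can replay the shipped Gating-ML against
the shipped preprocessed FCS and confirm the counts without external
state.  Problem sizes throughout (20,000 events/sample, two samples,
k = 6) keep a full build around two seconds while leaving every
population hundreds of events.

## Known limitations

- FCS: no ANALYSIS-segment semantics, no CRC verification, no
  vendor-specific keyword interpretation, no mixed-endian `$BYTEORD`.
- Gating: no quadrant/decision-tree/curly gates, no ratio transforms,
  no data-driven transform parameter estimation.
- ACS: checksums are not signatures; provenance is honest but not
  cryptographically attested.
- CLR: no class hierarchies; the header dialect is this package's
  pinned choice.
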