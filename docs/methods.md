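# Methods

## The memory model

The package models memory as a bank of *associative memory registers*:
boolean incidence tables of n feature columns × 2^m level rows over a
shared quantizer. The three primitives are exactly the relational
operations — write is set union of the table with the quantized instance
(λ), recognition is a per-cell material-implication test of the quantized
cue against the table (η), and retrieval draws one marked level per column
at random, centred on the cue (β). Because a register stores the *union*
of its instances, the set of functions it contains (one marked level per
column, any combination) is generally much larger than the set registered:
this is the source of both generalization (novel cues of the class are
recognized) and confusion (at high entropy, cues of other classes are
too). The computational entropy e(r) = (1/n) Σ log2 μ_i quantifies that
indeterminacy and is the single operating parameter worth watching.

Assumptions worth making explicit:

- Recognition is **one containment test per register** — rejection is
  O(bank size) and never iterative. This is the structural property that
  distinguishes the model from attractor memories.
- An unassigned cue feature constrains nothing (vacuous containment).
  A fully missing cue is therefore accepted by every register; callers
  who want to treat empty cues as invalid must do so upstream.
- The register to write into is an explicit label argument; the model
  presupposes an external attention mechanism and does not implement one.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `m_bits` | bit depth; 2^m levels per feature | 5 | 32-row registers are the smallest geometry with a satisfactory precision/recall compromise in the granularity sweep |
| `relax` | tolerated failing columns in η | 0 | strict containment; 1–3 of 64 (1.6–4.7%) restores recall on corrupted cues |
| `ReductionPolicy.mode` | β selection | `identity` | `triangular` makes retrieval constructive |
| `class_separation` | RMS per-feature distance between class means, in units of `within_spread` | 6.0 | well-separated clusters per feature — the regime where 5-bit level sets of different classes are essentially disjoint |
| `within_spread` | per-feature within-class standard deviation | 1.0 | sets the scale; only the ratio matters |
| `n_per_class` | corpus size per class | 1000 | see below |

## Quantization

Per-feature ranges are the observed min/max of the **training split** and
are then frozen: registration and test instances quantize through the same
affine map, and out-of-range values clip to the end bins rather than
erroring, because corrupted cues must still reach the containment test.
Bins are equal-width (level = ⌊(v − lo)/(hi − lo)·2^m⌋; dequantization
returns bin midpoints), keeping the digital/real conversion affine and
order-preserving; quantile binning was rejected for that reason. A
degenerate feature (hi = lo) always maps to level 0.

## The triangular retrieval kernel

β's "random distribution centred on the cue" is realized per column over
the marked set S_i: with c the cue's level (the median of S_i when the cue
is unassigned there) and d_max = max_{v∈S_i} |v − c|, level v gets weight
d_max + 1 − |v − c|, normalized. The +1 keeps every marked level reachable,
the peak sits exactly on the cue, and a singleton S_i reproduces the cue's
column deterministically, so the kernel degrades gracefully to the identity
policy at zero entropy. Non-contiguous marked sets are handled with no
special casing — weights depend only on distance to the centre. All
sampling flows from the `ReductionPolicy` seed; nothing touches global
random state.

## What the synthetic generator emulates — and what it does not

The generator stands in for an image corpus passed through a trained
convolutional encoder: class-conditional Gaussian clusters in 64 latent
features, balanced classes, three disjoint splits (57% train / 33%
remembered / 10% test, class-stratified, fold-rotated). Class means are
drawn once per seed from N(0, (sep·σ/√2)²) per feature, so the RMS
per-feature distance between two class means is sep·σ. Noise is
independent per feature — the minimal structure the memory assumes;
real encoder features are correlated and multi-modal, and nothing here
reproduces that.

Corpus size matters more than it may appear: recall at fine granularity is
a *coverage* property (a fresh cue must hit an already-marked level in all
64 columns). At 1,000 instances per class the remembered split holds 330
per class, the smallest desk scale at which the 32-row register shows the
published recall curve; at ~33 per class recall is zero at every useful m.
Consequently a green trend test establishes the qualitative entropy
trade-off, not any numeric point of the full-scale curves.

Occlusion is emulated in feature space (the pixel pathway and the encoder
are out of scope) in two modes that bracket an encoder's plausible
behaviour: `missing` (information absent — interacts with vacuous
containment and accepts everything, so it is not the experiment default)
and `background` (features replaced by draws from the pooled all-class
marginal). The occlusion experiment defaults to corrupting 3 of 64
features: heavy pixel occlusion reaches the registers only through an
encoder that reconstructs most latent features, and the 1–3-feature
relaxation sweep is informative exactly when the damage is on that scale —
at 32 corrupted features every cue is rejected at any relax ≤ 3.

## Numerical and design choices

- **Minimal-entropy selection, ties by bank order.** Minimal entropy is
  reported not to beat a uniform-random choice at coarse granularity; the
  deterministic tie-break is chosen for reproducibility. The random rule
  is available behind `selection="random"`.
- **Relaxation is an absolute failing-column count**; percentage input is
  floored (`relax_from_percent`), and counts print as percentages to one
  decimal (1/64 → 1.6%).
- **Precision conventions.** A register (or the whole system) that accepts
  nothing has produced no false positive; its precision is reported as 1.0,
  with an `all_rejected` flag at system level so the degenerate case is
  visible. Per-register averages are macro (unweighted over registers);
  micro is available behind `average="micro"`.
- **Identity-mode β with an off-support cue level** returns the nearest
  marked level (ties toward the lower level); an unassigned cue column
  with marks returns the level nearest the median mark.
- **Persistence** is a single JSON document (version, geometry, quantizer
  ranges, relax, one row-major 0/1 table per register) and round-trips
  bit-exactly; loading validates geometry per register and names the first
  offending field.

## Known limitations

- No encoder/decoder: inputs must already be feature vectors (CSV feature
  tables); an adapter from images is deliberately out of scope.
- Dense boolean tables only; no sparse representation, no weighted cells,
  no forgetting or decay.
- Registers are single-writer and banks homogeneous; overlapped-class
  registers are supported, but mixing overlapped and single-class
  registers in one bank is untested territory.
- The desk-scale experiment analogues validate orderings and monotone
  trends; they do not reproduce, and are not compared against, the
  full-scale published curves.
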