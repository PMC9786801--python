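# Methods

## Model and assumptions

The tool operates on three inputs: a feature→subnetwork map (GNPS
`clusterinfo_summary` dialect), per-feature in silico chemical-class
predictions over a three-level ontology (ClassyFire/ChemOnt superclass >
class > subclass), and per-feature spectral-library matches. The working
assumption is the one molecular networking itself rests on: features in a
subnetwork are structurally related, so their true chemical classes agree
at the shallower ontology levels far more often than chance. Under that
assumption a thresholded majority vote within a subnetwork is a
denoising step — individual in silico misclassifications are outvoted —
and propagating the winner to unannotated members is justified exactly
when the vote is decisive.

Votes are hierarchical and nested: the class vote counts
(superclass, class) label *prefixes* restricted to extend the winning
superclass, so the returned path is self-consistent by construction and a
deep label cannot win "across" subnetwork disagreement at a shallower
level. The vote denominator is all annotated nodes of the selected
source; nodes whose annotation is blank at the voted level stay in the
denominator and count against consensus. This is the conservative
reading: it lowers apparent consensus, trading annotation rate for a
lower false-positive rate, which is the tool's stated design goal. The
alternative (drop blank-at-level nodes from the denominator) is not
implemented as a switch; the engine is small enough that a fork of
`vote_level` covers that experiment.

Library matches outrank in silico predictions because a spectral match
is feature-level evidence with a structure behind it. By default a
library-sourced subnetwork that fails to reach consensus does **not**
fall back to its in silico annotations — the sources stay separate, which
is also what makes the no-library validation rerun meaningful. The
fallback exists behind `fallback_to_insilico` for users who prefer
coverage over strict source separation.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `t_superclass` | 0.50 | minimum agreeing fraction at superclass |
| `t_class`, `t_subclass` | 0.70 | stricter cutoffs at the narrower levels |
| `threshold_mode` | `at_least` | pass at the cutoff (≥) or only above it (>) |
| `fallback_to_insilico` | off | retry failed library votes with in silico votes |
| `singleton_sentinel` | −1 | componentindex value marking singletons |

Thresholds are fractions in (0, 1], independently overridable. The
default comparison is inclusive (`at_least`): "at least 50%" is the
operative phrasing, and the inclusive reading makes the 50% boundary at
even-sized subnetworks decidable by the tie rule rather than by the
comparison operator. A tie for the top count at any level truncates the
consensus above that level — deterministic and conservative.

Ambiguities resolved as design choices: the exported `score` is the
agreeing fraction at the *deepest passing level* ×100 (not an aggregate
across levels); "no votes at all" (`level=none`) is kept distinct from
"votes that disagree" (`level=no_consensus`), because an empty subnetwork
and a contested one are different facts; duplicate annotation rows for
one feature keep the most complete path, ties to first occurrence.

## Offline structure resolution

Classifying a library match's structure (SMILES/InChI) normally requires
a live ClassyFire/GNPS service. Here resolution goes through a local
4-column lookup table (`structure_key`, three levels) behind a small
interface, so runs are deterministic and testable offline; unknown keys
are explicit misses and the affected matches simply do not vote. Library
tables that already carry ontology columns bypass resolution entirely —
explicit labels win. The GNPS task fetcher validates the 32-hex task id
before any request, goes through one injectable transport function, and
caches raw bytes by task id; the exact endpoint shape varies across GNPS
workflow releases, so the assumed URL is documented at the definition and
nothing in the test suite touches the network.

## Synthetic studies: what they emulate and what they do not

The fixture generator plants, per subnetwork, a true full path, then
realizes exact per-level agreement counts `ceil(purity × n_annotated)`
(ceiling, so `at_least` boundaries are exactly hittable). Nodes diverging
below a level receive *sibling* labels under the shared parent —
mimicking related compounds that differ at finer levels, and exercising
the truncation logic. Siblings are assigned round-robin over a
seed-shuffled sibling list rather than iid: this keeps discrepant labels
spread (no accidental competing majority), which is what makes exhaustive
recovery/rejection checks exact. In silico labels can then be corrupted
feature-wise at a known flip rate to a uniformly chosen path under a
different superclass. All randomness flows through one seeded generator;
identical spec + seed yields byte-identical fixture files.

Default study conditions: 60 subnetworks of 2–12 nodes, 20 singletons, a
6×4×3 ontology, purity (0.90, 0.85, 0.80), 80% of nodes annotated, 30%
library coverage. These are desk-scale stand-ins for real networking jobs
(which run to ~10⁴ features and ~10³–10⁴ subnetworks); the acceptance
script scales to 400 subnetworks, and the parameter-recovery study uses
600 two-node subnetworks with exactly one annotated node each, so that
each subnetwork contributes one independent Bernoulli(1−ε) comparison and
the binomial standard error of the measured TPR is exact. With larger
subnetworks, flips would cluster within components and the feature-level
binomial error model would understate the variance.

What the generator does **not** emulate: mass spectra, cosine-similarity
network topology, retention times, CANOPUS posterior calibration, or —
importantly — features the predictor declines to annotate in a
class-dependent way. Because every subnetwork gets at least one
annotation and purities are set well above the cutoffs, synthetic
annotation rates approach 100%, far above what real datasets show (where
in silico coverage and agreement are the binding constraints). Passing
tests therefore demonstrate the correctness of the voting, propagation
and bookkeeping machinery under known ground truth — not the field
performance of consensus annotation on real networks.

## Validation statistics

The TPR rerun withholds library matches from voting and compares, per
ontology level, the propagated consensus label against the withheld
library label; a feature is evaluable at a level only when both labels
are non-empty, and levels with no evaluable features are reported as
undefined rather than 0 or 1. The cross-level aggregate is mean ± sample
standard deviation (ddof = 1) over the three level-wise TPRs; per-level
counts are always emitted so other aggregations can be recomputed.
Annotation rates follow the network-figure convention of excluding
singleton ("single-loop") nodes, with an all-features variant emitted
alongside; expansion is reported both as percent increase over
library-only counts and as a plain ratio ×100, since either arithmetic is
seen in practice. Mean consensus averages each subnetwork's score once,
regardless of subnetwork size. Class abundance sums feature intensity by
consensus superclass per sample and normalizes classified signal to
100%; unclassified features never enter the denominator, and an all-zero
sample is undefined (NaN), not zero.

## Numerical and degenerate-input choices

Label normalization strips and collapses whitespace, maps null sentinels
("", "NA", "N/A", "no prediction", "null", case-insensitive) to the
empty label, and compares case-insensitively while preserving the first
display form seen in feature-id order. Records violating prefix closure
(a label below an empty level) are repaired by blanking the deeper
levels, with the repair logged. Exported scores carry two decimals; full
precision stays in memory, so write→read→write is byte-stable after the
first quantization. Size-1 "components" with a non-sentinel id are
reclassified as singletons with a warning. `ceil` on purity×n is applied
after rounding at 1e-9 to keep binary float noise from shifting exact
boundaries. Feature ids must be integral; SIRIUS id strings are accepted
by extracting the trailing integer.

## Known limitations

Only the three ClassyFire levels are modeled (no 11-level ChemOnt, no
CHEMONTIDs); no chemical-structure parsing or InChI↔SMILES conversion;
the GNPS fetcher assumes one endpoint shape; and the validation TPR, as
in any such scheme, is computed on the well-characterized subset of
features that have library matches, which may flatter in silico tools
trained on the same libraries.
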