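"""Deterministic synthetic fixtures with planted consensus structure.

Generates networks, ontologies and annotation tables that emulate the
statistical structure molecular networking assumes: subnetworks group
structurally similar compounds, so their members share ontology prefixes,
diverging more often at the finer class/subclass levels than at
superclass.  Every label, structure key and intensity here is synthetic
(``SC1.C2.S3``-style vocabulary, ``SYN-…`` keys) — no spectra, cosine
scores or retention times are simulated.

The planted ground truth (per-subnetwork path and exact per-level vote
counts) makes the expected engine output computable by hand, which is what
the recovery/rejection and parameter-recovery tests lean on.  All
randomness flows through one seeded generator: identical spec + seed means
byte-identical fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io_gnps import SINGLETON_SENTINEL, NetworkAssignment
from .ontology import FeatureAnnotation, OntologyLookup, OntologyPath, Source

__all__ = [
    "FixtureSpec",
    "Vocabulary",
    "PlantedComponent",
    "FixtureBundle",
    "generate_ontology",
    "generate_network",
    "write_fixture_dir",
]

FIXTURE_FILES = (
    "network_info.tsv",
    "canopus_summary.tsv",
    "library_matches.tsv",
    "ontology_lookup.tsv",
    "ground_truth.tsv",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    ``purity`` gives, per level, the fraction of a subnetwork's annotated
    nodes that carry the planted label at that level (realized exactly,
    via ceiling, so threshold boundaries are hittable).
    ``annotation_coverage`` is the fraction of each subnetwork's nodes
    that are annotated at all; ``library_coverage`` the fraction of
    subnetworks (and of singletons) given a library match.
    ``label_flip_rate`` corrupts each in silico annotation, independently,
    to a uniformly chosen path under a different superclass — the knob the
    true-positive-rate recovery study turns.
    """

    n_components: int = 60
    component_size_range: tuple[int, int] = (2, 12)
    n_singletons: int = 20
    ontology_shape: tuple[int, int, int] = (6, 4, 3)
    purity: tuple[float, float, float] = (0.9, 0.85, 0.8)
    library_coverage: float = 0.3
    annotation_coverage: float = 0.8
    label_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise InputError("n_components must be positive")
        lo, hi = self.component_size_range
        if lo < 2 or hi < lo:
            raise InputError(
                "component_size_range must satisfy 2 <= min <= max "
                f"(got {self.component_size_range})"
            )
        if self.n_singletons < 0:
            raise InputError("n_singletons must be non-negative")
        if any(n < 1 for n in self.ontology_shape):
            raise InputError("ontology_shape counts must be positive")
        for name in ("library_coverage", "annotation_coverage", "label_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        for p in self.purity:
            if not 0.0 <= p <= 1.0:
                raise InputError(f"purity fractions must be in [0, 1], got {p}")
        if not (self.purity[0] >= self.purity[1] >= self.purity[2]):
            raise InputError(
                "purity must be non-increasing with depth: nodes carrying the "
                "planted class must also carry the planted superclass "
                f"(got {self.purity})"
            )


@dataclass(frozen=True)
class Vocabulary:
    """Synthetic nested label vocabulary; children embed their parents
    (``SC1`` > ``SC1.C2`` > ``SC1.C2.S3``), so the parent is recoverable
    from any child label."""

    superclasses: tuple[str, ...]
    classes: dict[str, tuple[str, ...]]
    subclasses: dict[str, tuple[str, ...]]

    def full_paths(self) -> list[OntologyPath]:
        out = []
        for sc in self.superclasses:
            for cl in self.classes[sc]:
                for sub in self.subclasses[cl]:
                    out.append(OntologyPath(sc, cl, sub))
        return out


def structure_key_for(path: OntologyPath) -> str:
    """Synthetic structure key standing in for a SMILES/InChI string."""
    return f"SYN-{path.subclass}"


def generate_ontology(
    shape: tuple[int, int, int], seed: int = 0
) -> tuple[OntologyLookup, Vocabulary]:
    """Build a synthetic three-level vocabulary and its structure lookup.

    ``shape = (n_superclasses, classes_per_superclass,
    subclasses_per_class)``.  Construction is deterministic; the seed is
    accepted for interface symmetry with :func:`generate_network`.
    """
    n_sc, n_cl, n_sub = shape
    if n_sc < 1 or n_cl < 1 or n_sub < 1:
        raise InputError(f"ontology shape counts must be positive, got {shape}")
    superclasses = tuple(f"SC{i}" for i in range(1, n_sc + 1))
    classes = {
        sc: tuple(f"{sc}.C{j}" for j in range(1, n_cl + 1)) for sc in superclasses
    }
    subclasses = {
        cl: tuple(f"{cl}.S{k}" for k in range(1, n_sub + 1))
        for sc in superclasses
        for cl in classes[sc]
    }
    vocab = Vocabulary(superclasses, classes, subclasses)
    lookup = OntologyLookup(
        {structure_key_for(p): p for p in vocab.full_paths()}
    )
    return lookup, vocab


@dataclass(frozen=True)
class PlantedComponent:
    """Ground truth for one subnetwork.

    ``level_counts`` are the exact numbers of annotated nodes carrying the
    planted label at (superclass, class, subclass) *before* any label
    flipping; with ``label_flip_rate == 0`` the engine's vote fractions
    are exactly ``level_counts / n_annotated``.
    """

    component_id: int
    path: OntologyPath
    size: int
    n_annotated: int
    level_counts: tuple[int, int, int]
    n_flipped: int = 0
    library_feature: Optional[int] = None

    def expected_level(
        self, thresholds: Sequence[float], at_least: bool = True
    ) -> str:
        """Consensus level the engine must return (valid when unflipped)."""
        level = "no_consensus"
        names = ("superclass", "class", "subclass")
        for i, (c, t) in enumerate(zip(self.level_counts, thresholds)):
            frac = c / self.n_annotated if self.n_annotated else 0.0
            ok = frac >= t if at_least else frac > t
            if not ok:
                break
            level = names[i]
        return level


@dataclass
class FixtureBundle:
    """Everything one synthetic study produced, in memory."""

    spec: FixtureSpec
    network: NetworkAssignment
    library_annotations: list[FeatureAnnotation]
    insilico_annotations: list[FeatureAnnotation]
    truth_annotations: list[FeatureAnnotation]
    lookup: OntologyLookup
    vocabulary: Vocabulary
    planted: list[PlantedComponent]
    singleton_truth: dict[int, OntologyPath] = field(default_factory=dict)


def _ceil(x: float) -> int:
    # round first so 0.6*5 == 3.0000000000000004 does not ceil to 4
    return math.ceil(round(x, 9))


def _round_robin(
    rng: np.random.Generator, options: Sequence, n: int
) -> list:
    """n picks cycling through a seed-shuffled option list.

    Spreads discrepant labels as evenly as possible so no sibling can
    accumulate an accidental competing majority.
    """
    order = list(options)
    perm = rng.permutation(len(order))
    return [order[perm[i % len(order)]] for i in range(n)]


def _planted_paths(
    rng: np.random.Generator,
    vocab: Vocabulary,
    planted: OntologyPath,
    n_ann: int,
    counts: tuple[int, int, int],
) -> list[OntologyPath]:
    """Per-node true paths realizing the planted per-level counts."""
    c0, c1, c2 = counts
    paths: list[OntologyPath] = [planted] * c2
    if c1 > c2:
        sibs = [s for s in vocab.subclasses[planted.class_] if s != planted.subclass]
        if not sibs:
            raise InputError(
                "cannot realize subclass purity < class purity: ontology has "
                "a single subclass per class"
            )
        for sub in _round_robin(rng, sibs, c1 - c2):
            paths.append(OntologyPath(planted.superclass, planted.class_, sub))
    if c0 > c1:
        sib_classes = [
            c for c in vocab.classes[planted.superclass] if c != planted.class_
        ]
        if not sib_classes:
            raise InputError(
                "cannot realize class purity < superclass purity: ontology "
                "has a single class per superclass"
            )
        for cl in _round_robin(rng, sib_classes, c0 - c1):
            sub = vocab.subclasses[cl][rng.integers(len(vocab.subclasses[cl]))]
            paths.append(OntologyPath(planted.superclass, cl, sub))
    if n_ann > c0:
        sib_sc = [s for s in vocab.superclasses if s != planted.superclass]
        if not sib_sc:
            raise InputError(
                "cannot realize superclass purity < 1: ontology has a single "
                "superclass"
            )
        for sc in _round_robin(rng, sib_sc, n_ann - c0):
            cl = vocab.classes[sc][rng.integers(len(vocab.classes[sc]))]
            sub = vocab.subclasses[cl][rng.integers(len(vocab.subclasses[cl]))]
            paths.append(OntologyPath(sc, cl, sub))
    perm = rng.permutation(n_ann)
    return [paths[i] for i in perm]


def _flip_path(
    rng: np.random.Generator, vocab: Vocabulary, true_path: OntologyPath
) -> OntologyPath:
    """Corrupt to a uniformly chosen path under a different superclass."""
    others = [s for s in vocab.superclasses if s != true_path.superclass]
    if not others:
        raise InputError("label flipping requires at least two superclasses")
    sc = others[rng.integers(len(others))]
    cl = vocab.classes[sc][rng.integers(len(vocab.classes[sc]))]
    sub = vocab.subclasses[cl][rng.integers(len(vocab.subclasses[cl]))]
    return OntologyPath(sc, cl, sub)


def generate_network(spec: FixtureSpec) -> FixtureBundle:
    """Generate one synthetic study with planted consensus structure.

    Per subnetwork: a planted full path is drawn; ``ceil(purity × n
    annotated)`` voting nodes carry the planted label at each level (the
    segments diverging below a level receive *sibling* labels under the
    shared parent, mimicking chemically related compounds that differ at
    finer ontology levels); in silico labels are then flipped with the
    spec's flip rate.  Library matches (structure keys resolving through
    the generated lookup) are given to a ``library_coverage`` share of
    subnetworks and singletons, always carrying the node's true path.
    """
    rng = np.random.default_rng(spec.seed)
    lookup, vocab = generate_ontology(spec.ontology_shape, spec.seed)
    all_paths = vocab.full_paths()

    component_of: dict[int, int] = {}
    insilico: list[FeatureAnnotation] = []
    truth: list[FeatureAnnotation] = []
    planted_out: list[PlantedComponent] = []
    # component_id -> (annotated feature ids, their true paths)
    annotated_by_comp: dict[int, tuple[list[int], list[OntologyPath]]] = {}

    next_fid = 1
    lo, hi = spec.component_size_range
    for comp_id in range(1, spec.n_components + 1):
        size = int(rng.integers(lo, hi + 1))
        feats = list(range(next_fid, next_fid + size))
        next_fid += size
        for f in feats:
            component_of[f] = comp_id

        n_ann = min(size, _ceil(spec.annotation_coverage * size))
        counts = tuple(_ceil(p * n_ann) for p in spec.purity)
        if n_ann == 0:
            planted_out.append(
                PlantedComponent(comp_id, OntologyPath(), size, 0, (0, 0, 0))
            )
            annotated_by_comp[comp_id] = ([], [])
            continue
        planted = all_paths[rng.integers(len(all_paths))]
        true_paths = _planted_paths(rng, vocab, planted, n_ann, counts)  # type: ignore[arg-type]
        ann_idx = rng.choice(size, size=n_ann, replace=False)
        ann_feats = sorted(feats[i] for i in ann_idx)

        n_flipped = 0
        for f, tp in zip(ann_feats, true_paths):
            observed = tp
            if spec.label_flip_rate > 0 and rng.random() < spec.label_flip_rate:
                observed = _flip_path(rng, vocab, tp)
                n_flipped += 1
            insilico.append(FeatureAnnotation(f, Source.IN_SILICO, observed))
            truth.append(FeatureAnnotation(f, Source.LIBRARY, tp))
        planted_out.append(
            PlantedComponent(comp_id, planted, size, n_ann, counts, n_flipped)  # type: ignore[arg-type]
        )
        annotated_by_comp[comp_id] = (ann_feats, true_paths)

    # singletons
    singleton_truth: dict[int, OntologyPath] = {}
    singleton_fids = list(range(next_fid, next_fid + spec.n_singletons))
    next_fid += spec.n_singletons
    for f in singleton_fids:
        component_of[f] = SINGLETON_SENTINEL
        tp = all_paths[rng.integers(len(all_paths))]
        singleton_truth[f] = tp
        observed = tp
        if spec.label_flip_rate > 0 and rng.random() < spec.label_flip_rate:
            observed = _flip_path(rng, vocab, tp)
        insilico.append(FeatureAnnotation(f, Source.IN_SILICO, observed))

    # library matches: a share of components, and a share of singletons
    library: list[FeatureAnnotation] = []
    eligible = [c for c in range(1, spec.n_components + 1) if annotated_by_comp[c][0]]
    n_lib_comp = min(len(eligible), _ceil(spec.library_coverage * spec.n_components))
    lib_comps = sorted(
        rng.choice(eligible, size=n_lib_comp, replace=False).tolist()
    )
    lib_feature_of: dict[int, int] = {}
    for comp_id in lib_comps:
        ann_feats, true_paths = annotated_by_comp[comp_id]
        pick = int(rng.integers(len(ann_feats)))
        f, tp = ann_feats[pick], true_paths[pick]
        library.append(
            FeatureAnnotation(
                f,
                Source.LIBRARY,
                tp,
                structure_key=structure_key_for(tp),
                compound_name=f"Synthetic compound {f}",
            )
        )
        lib_feature_of[comp_id] = f
    n_lib_single = _ceil(spec.library_coverage * spec.n_singletons)
    if n_lib_single:
        for f in sorted(
            rng.choice(singleton_fids, size=n_lib_single, replace=False).tolist()
        ):
            tp = singleton_truth[f]
            library.append(
                FeatureAnnotation(
                    f,
                    Source.LIBRARY,
                    tp,
                    structure_key=structure_key_for(tp),
                    compound_name=f"Synthetic compound {f}",
                )
            )

    planted_out = [
        replace(pc, library_feature=lib_feature_of.get(pc.component_id))
        for pc in planted_out
    ]
    return FixtureBundle(
        spec=spec,
        network=NetworkAssignment(component_of),
        library_annotations=library,
        insilico_annotations=insilico,
        truth_annotations=truth,
        lookup=lookup,
        vocabulary=vocab,
        planted=planted_out,
        singleton_truth=singleton_truth,
    )


def write_fixture_dir(bundle: FixtureBundle, out_dir: Path | str) -> Path:
    """Write a fixture directory in the dialects the readers accept.

    Files: ``network_info.tsv``, ``canopus_summary.tsv`` (generic
    dialect), ``library_matches.tsv`` (structure keys resolving through
    ``ontology_lookup.tsv``), and ``ground_truth.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = pd.DataFrame(
        {
            "cluster index": bundle.network.features,
            "componentindex": [
                bundle.network.component_of[f] for f in bundle.network.features
            ],
        }
    )
    net.to_csv(out / "network_info.tsv", sep="\t", index=False, lineterminator="\n")

    sil = pd.DataFrame(
        [
            {
                "featureNumber": a.feature_id,
                "superclass": a.path.superclass,
                "class": a.path.class_,
                "subclass": a.path.subclass,
            }
            for a in sorted(bundle.insilico_annotations, key=lambda a: a.feature_id)
        ],
        columns=["featureNumber", "superclass", "class", "subclass"],
    )
    sil.to_csv(out / "canopus_summary.tsv", sep="\t", index=False, lineterminator="\n")

    lib = pd.DataFrame(
        [
            {
                "featureNumber": a.feature_id,
                "Compound_Name": a.compound_name or "",
                "structure_key": a.structure_key or "",
            }
            for a in sorted(bundle.library_annotations, key=lambda a: a.feature_id)
        ],
        columns=["featureNumber", "Compound_Name", "structure_key"],
    )
    lib.to_csv(
        out / "library_matches.tsv", sep="\t", index=False, lineterminator="\n"
    )

    look = pd.DataFrame(
        [
            {
                "structure_key": k,
                "superclass": p.superclass,
                "class": p.class_,
                "subclass": p.subclass,
            }
            for k, p in sorted(bundle.lookup.mapping.items())
        ],
        columns=["structure_key", "superclass", "class", "subclass"],
    )
    look.to_csv(
        out / "ontology_lookup.tsv", sep="\t", index=False, lineterminator="\n"
    )

    gt = pd.DataFrame(
        [
            {
                "component_id": pc.component_id,
                "superclass": pc.path.superclass,
                "class": pc.path.class_,
                "subclass": pc.path.subclass,
                "size": pc.size,
                "n_annotated": pc.n_annotated,
                "c_superclass": pc.level_counts[0],
                "c_class": pc.level_counts[1],
                "c_subclass": pc.level_counts[2],
                "n_flipped": pc.n_flipped,
                "library_feature": (
                    "" if pc.library_feature is None else pc.library_feature
                ),
            }
            for pc in bundle.planted
        ]
    )
    gt.to_csv(out / "ground_truth.tsv", sep="\t", index=False, lineterminator="\n")
    return out


def random_intensities(
    bundle: FixtureBundle, n_samples: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Synthetic features×samples intensity table (log-normal XIC areas)."""
    rng = np.random.default_rng(seed)
    feats = bundle.network.features
    data = rng.lognormal(mean=10.0, sigma=1.0, size=(len(feats), n_samples))
    return pd.DataFrame(
        data, index=pd.Index(feats, name="feature_id"),
        columns=[f"sample_{i + 1}" for i in range(n_samples)],
    )
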