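"""The consensus-annotation engine.

For every molecular subnetwork the engine (1) selects the annotation
source — spectral-library matches outrank in silico class predictions —
(2) runs a thresholded majority vote down the superclass > class >
subclass hierarchy, accepting the most granular level that passes its
cutoff and every shallower cutoff, and (3) propagates the winning path to
every member feature, annotated or not.  Singleton nodes (no network
neighbors) only ever receive their own library match: an in silico
annotation is never propagated to a singleton, which keeps the false
positive rate down.

The default cutoffs are 50% at superclass and a stricter 70% at class and
subclass; a subnetwork whose votes cannot clear the superclass cutoff is
reported as "no consensus reached".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConsistencyError, InputError
from .io_gnps import SINGLETON_SENTINEL, ConsensusRow, NetworkAssignment
from .ontology import (
    EMPTY_PATH,
    LEVELS,
    FeatureAnnotation,
    OntologyPath,
    Source,
    dedupe_annotations,
)

logger = logging.getLogger(__name__)

NO_CONSENSUS = "no_consensus"

#: Paper-default per-level consensus cutoffs, shallowest first.
DEFAULT_THRESHOLDS = (0.50, 0.70, 0.70)


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds and behavioral switches.

    ``t_superclass``/``t_class``/``t_subclass`` are fractions in (0, 1];
    defaults are the shipped 50%/70%/70%.  ``threshold_mode`` selects
    whether a vote passes at exactly the cutoff (``at_least``, default) or
    must exceed it (``strictly_greater``).  ``fallback_to_insilico`` lets
    a library-sourced subnetwork that reaches no consensus retry with its
    in silico annotations (off by default: sources stay separate).
    """

    t_superclass: float = DEFAULT_THRESHOLDS[0]
    t_class: float = DEFAULT_THRESHOLDS[1]
    t_subclass: float = DEFAULT_THRESHOLDS[2]
    threshold_mode: str = "at_least"
    fallback_to_insilico: bool = False
    singleton_sentinel: int = SINGLETON_SENTINEL

    def __post_init__(self) -> None:
        for name, t in zip(
            ("t_superclass", "t_class", "t_subclass"), self.thresholds
        ):
            if not (0.0 < t <= 1.0):
                raise InputError(f"{name} must be in (0, 1], got {t}")
        if self.threshold_mode not in ("at_least", "strictly_greater"):
            raise InputError(
                f"threshold_mode must be 'at_least' or 'strictly_greater', "
                f"got {self.threshold_mode!r}"
            )

    @property
    def thresholds(self) -> tuple[float, float, float]:
        return (self.t_superclass, self.t_class, self.t_subclass)

    def passes(self, fraction: float, level: int) -> bool:
        t = self.thresholds[level]
        return fraction >= t if self.threshold_mode == "at_least" else fraction > t


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome for one subnetwork.

    ``level`` is a level name or ``no_consensus``; ``path`` is truncated
    at ``level``; ``score`` is the consensus fraction at that level ×100
    (None iff no consensus); ``n_nodes`` counts the voting (annotated)
    nodes from the selected source.
    """

    component_id: int
    level: str
    path: OntologyPath
    score: Optional[float]
    n_nodes: int
    source: Source


def select_source(
    component_features: Sequence[int],
    library_anns: Mapping[int, FeatureAnnotation],
    insilico_anns: Mapping[int, FeatureAnnotation],
) -> Source:
    """Pick the annotation source for one subnetwork.

    Library matches are used before in silico annotations: ``library`` iff
    at least one voting-eligible library annotation exists among the
    member features, else ``in_silico`` iff any in silico annotation
    exists, else ``none``.
    """
    feats = set(component_features)
    if any(f in library_anns and library_anns[f].votes for f in feats):
        return Source.LIBRARY
    if any(f in insilico_anns and insilico_anns[f].votes for f in feats):
        return Source.IN_SILICO
    return Source.NONE


def vote_level(
    paths: Sequence[OntologyPath],
    level: int,
    required_prefix: tuple[str, ...] = (),
) -> tuple[Optional[str], float]:
    """Majority vote at one hierarchy level, nested under a fixed prefix.

    Counts, over ALL voting paths (the denominator is every annotated node
    of the selected source, including nodes that are blank at this level),
    the most frequent length-``level+1`` label prefix extending
    ``required_prefix`` (case-insensitive keys).  Empty labels never win.
    Returns ``(winner display label, fraction)``; a tie for the top count
    returns ``(None, top fraction)``.
    """
    if not paths:
        raise InputError("vote_level called with no voting paths")
    if not 0 <= level < len(LEVELS):
        raise InputError(f"level index out of range: {level}")
    counts: dict[tuple[str, ...], int] = {}
    display: dict[tuple[str, ...], str] = {}
    for p in paths:
        key = p.key()
        if key[:level] != required_prefix or not key[level]:
            continue
        cand = key[: level + 1]
        counts[cand] = counts.get(cand, 0) + 1
        display.setdefault(cand, p.label_at(level))
    if not counts:
        return None, 0.0
    top = max(counts.values())
    winners = [k for k, c in counts.items() if c == top]
    fraction = top / len(paths)
    if len(winners) > 1:
        return None, fraction
    return display[winners[0]], fraction


def derive_consensus(
    component_id: int,
    paths: Sequence[OntologyPath],
    config: ConsensusConfig,
    source: Source,
) -> ConsensusResult:
    """Walk the hierarchy and keep the deepest level that passes.

    Votes superclass, then class, then subclass, each constrained to
    extend the shallower winner, stopping at the first level that fails
    its cutoff (or ties).  A failure already at superclass yields
    ``no_consensus`` with an empty path.  The score is the fraction at the
    deepest passing level ×100.
    """
    if not paths:
        raise InputError(
            f"derive_consensus called for component {component_id} with no "
            "annotated nodes; select_source must return none first"
        )
    prefix: tuple[str, ...] = ()
    labels: list[str] = []
    fractions: list[float] = []
    for level in range(len(LEVELS)):
        winner, fraction = vote_level(paths, level, prefix)
        if winner is None or not config.passes(fraction, level):
            break
        labels.append(winner)
        fractions.append(fraction)
        prefix = prefix + (winner.casefold(),)
    if not labels:
        return ConsensusResult(
            component_id, NO_CONSENSUS, EMPTY_PATH, None, len(paths), source
        )
    path = OntologyPath(*(labels + [""] * (3 - len(labels))))
    return ConsensusResult(
        component_id,
        LEVELS[len(labels) - 1],
        path,
        100.0 * fractions[-1],
        len(paths),
        source,
    )


def handle_singleton(
    feature_id: int, library_anns: Mapping[int, FeatureAnnotation]
) -> ConsensusRow:
    """Annotate a singleton node.

    A singleton receives its own library annotation when one exists
    (full path, no score, one node); otherwise it stays unannotated.
    In silico annotations are NEVER applied to singletons.
    """
    ann = library_anns.get(feature_id)
    if ann is not None and ann.votes:
        depth = ann.path.depth()
        return ConsensusRow(
            feature_id=feature_id,
            path=ann.path,
            score=None,
            level=LEVELS[depth - 1],
            n_nodes=1,
            source=Source.LIBRARY,
        )
    return ConsensusRow(feature_id=feature_id)


def propagate(
    network: NetworkAssignment,
    results: Mapping[int, ConsensusResult],
    library_anns: Mapping[int, FeatureAnnotation],
) -> list[ConsensusRow]:
    """Spread each subnetwork's consensus to every member feature.

    Every feature of a component receives the component's consensus path,
    score, level and source — including features that had no annotation of
    their own (this is the propagation).  Singletons go through
    :func:`handle_singleton`.  Components with no result at all (nothing
    voted) yield rows with level ``none``.  Output has exactly one row per
    network feature, ordered by feature id.
    """
    known = set(network.components())
    orphans = set(results) - known
    if orphans:
        raise ConsistencyError(
            f"consensus results reference unknown component(s): {sorted(orphans)}"
        )
    rows: list[ConsensusRow] = []
    for fid in network.features:
        comp = network.component_of[fid]
        if comp == network.singleton_sentinel:
            row = handle_singleton(fid, library_anns)
            row.component_id = comp
            rows.append(row)
            continue
        res = results.get(comp)
        if res is None:
            rows.append(ConsensusRow(feature_id=fid, component_id=comp))
        else:
            rows.append(
                ConsensusRow(
                    feature_id=fid,
                    path=res.path,
                    score=res.score,
                    level=res.level,
                    n_nodes=res.n_nodes,
                    source=res.source,
                    component_id=comp,
                )
            )
    return rows


def _voting_paths(
    features: Sequence[int], anns: Mapping[int, FeatureAnnotation]
) -> list[OntologyPath]:
    return [anns[f].path for f in features if f in anns and anns[f].votes]


def run_concise(
    network: NetworkAssignment,
    library_anns: Iterable[FeatureAnnotation] | Mapping[int, FeatureAnnotation],
    insilico_anns: Iterable[FeatureAnnotation] | Mapping[int, FeatureAnnotation],
    config: Optional[ConsensusConfig] = None,
) -> list[ConsensusRow]:
    """End-to-end run: source selection, voting, propagation.

    Deterministic: identical inputs and config produce identical rows.
    With ``config.fallback_to_insilico``, a library-sourced subnetwork
    that reaches no consensus retries with its in silico annotations and
    keeps that result if the retry passes.
    """
    config = config or ConsensusConfig()
    lib = (
        dict(library_anns)
        if isinstance(library_anns, Mapping)
        else dedupe_annotations(library_anns)
    )
    sil = (
        dict(insilico_anns)
        if isinstance(insilico_anns, Mapping)
        else dedupe_annotations(insilico_anns)
    )
    results: dict[int, ConsensusResult] = {}
    for comp, feats in network.components().items():
        source = select_source(feats, lib, sil)
        if source is Source.NONE:
            continue
        anns = lib if source is Source.LIBRARY else sil
        res = derive_consensus(comp, _voting_paths(feats, anns), config, source)
        if (
            res.level == NO_CONSENSUS
            and source is Source.LIBRARY
            and config.fallback_to_insilico
        ):
            fallback_paths = _voting_paths(feats, sil)
            if fallback_paths:
                retry = derive_consensus(comp, fallback_paths, config, Source.IN_SILICO)
                if retry.level != NO_CONSENSUS:
                    res = retry
        results[comp] = res
    n_reached = sum(1 for r in results.values() if r.level != NO_CONSENSUS)
    logger.info(
        "consensus: %d/%d annotated subnetworks reached consensus",
        n_reached,
        len(results),
    )
    return propagate(network, results, lib)
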