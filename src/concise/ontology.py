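"""Domain types for the three-level ChemOnt hierarchy.

ConCISE compares chemical-class annotations at the ClassyFire/ChemOnt
superclass, class and subclass levels.  This module defines the canonical
in-memory representation of such a three-level ontology path, the
per-feature annotation record, and the local structure-key -> ontology
lookup used to classify spectral-library matches offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .errors import InputError

logger = logging.getLogger(__name__)

#: Ordered level names of the hierarchy, shallowest first.
LEVELS: tuple[str, str, str] = ("superclass", "class", "subclass")

#: Strings that mean "no annotation" in the wild (SIRIUS/CANOPUS dialects
#: differ); compared case-insensitively after whitespace normalization.
DEFAULT_NULL_SENTINELS: frozenset[str] = frozenset(
    {"", "na", "n/a", "no prediction", "null"}
)


class Source(str, Enum):
    """Where an annotation came from; library matches outrank in silico."""

    LIBRARY = "library"
    IN_SILICO = "in_silico"
    NONE = "none"


def normalize_label(
    raw: object, sentinels: frozenset[str] = DEFAULT_NULL_SENTINELS
) -> str:
    """Canonicalize one ontology label.

    Surrounding whitespace is stripped, internal whitespace collapsed to a
    single space, and null-like sentinels (``""``, ``"NA"``, ``"N/A"``,
    ``"no prediction"``, ``"null"``, case-insensitive) map to the empty
    label.  ``None`` and NaN map to the empty label too.  Total function:
    never raises.  Idempotent.
    """
    if raw is None:
        return ""
    if not isinstance(raw, str):
        # pandas hands us float('nan') for empty TSV cells
        if raw != raw:  # NaN
            return ""
        raw = str(raw)
    collapsed = " ".join(raw.split())
    if collapsed.casefold() in sentinels:
        return ""
    return collapsed


@dataclass(frozen=True)
class OntologyPath:
    """An ordered (superclass, class, subclass) label triple.

    Labels are stored in normalized display form; comparisons between
    labels are case-insensitive (see :meth:`key`).  A valid path is
    prefix-closed: a non-empty label never sits below an empty one.
    Construct through :func:`make_path`, which normalizes and repairs.
    """

    superclass: str = ""
    class_: str = ""
    subclass: str = ""

    def labels(self) -> tuple[str, str, str]:
        return (self.superclass, self.class_, self.subclass)

    def key(self) -> tuple[str, str, str]:
        """Case-insensitive comparison key."""
        return tuple(s.casefold() for s in self.labels())  # type: ignore[return-value]

    def depth(self) -> int:
        """Number of leading non-empty levels (0..3)."""
        n = 0
        for label in self.labels():
            if not label:
                break
            n += 1
        return n

    @property
    def is_empty(self) -> bool:
        return self.depth() == 0

    def truncate(self, depth: int) -> "OntologyPath":
        """Keep the first ``depth`` levels, blanking the rest."""
        kept = [lab if i < depth else "" for i, lab in enumerate(self.labels())]
        return OntologyPath(*kept)

    def label_at(self, level: int) -> str:
        return self.labels()[level]


EMPTY_PATH = OntologyPath()


def make_path(
    superclass: object,
    class_: object,
    subclass: object,
    sentinels: frozenset[str] = DEFAULT_NULL_SENTINELS,
) -> tuple[OntologyPath, bool]:
    """Build a normalized, prefix-closed path from three raw labels.

    Returns ``(path, repaired)`` where *repaired* is True when a label had
    to be blanked because a shallower level was empty (the record violated
    prefix closure).  Never raises.
    """
    labels = [normalize_label(x, sentinels) for x in (superclass, class_, subclass)]
    repaired = False
    for i in (1, 2):
        if labels[i] and not labels[i - 1]:
            # blank this level and everything below it
            for j in range(i, 3):
                if labels[j]:
                    repaired = True
                labels[j] = ""
            break
    return OntologyPath(*labels), repaired


@dataclass(frozen=True)
class FeatureAnnotation:
    """One feature's annotation from one source.

    ``feature_id`` is the positive integer GNPS cluster index.  A library
    annotation is only eligible for consensus voting when it carries
    structural information (SMILES/InChI) or explicit ontology labels; by
    the time a :class:`FeatureAnnotation` exists its ``path`` reflects
    whichever was available.
    """

    feature_id: int
    source: Source
    path: OntologyPath
    structure_key: Optional[str] = None
    compound_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.feature_id <= 0:
            raise InputError(f"feature_id must be positive, got {self.feature_id}")

    @property
    def votes(self) -> bool:
        """Whether this annotation can participate in consensus voting."""
        return not self.path.is_empty


def dedupe_annotations(
    annotations: Iterable[FeatureAnnotation],
) -> dict[int, FeatureAnnotation]:
    """Collapse to exactly one annotation per feature id.

    When several rows annotate the same feature, the one with the most
    complete path (most non-empty levels) wins; ties break to the first
    occurrence in input order.  Deduplication events are logged.
    """
    best: dict[int, FeatureAnnotation] = {}
    n_dropped = 0
    for ann in annotations:
        prev = best.get(ann.feature_id)
        if prev is None:
            best[ann.feature_id] = ann
        else:
            n_dropped += 1
            if ann.path.depth() > prev.path.depth():
                best[ann.feature_id] = ann
    if n_dropped:
        logger.info("deduplicated %d duplicate annotation rows", n_dropped)
    return best


@dataclass
class OntologyLookup:
    """Local structure-key -> ontology-path table.

    Stands in for live ClassyFire classification of library-match
    structures so runs are deterministic and offline.  Keys are stored
    whitespace-stripped; an unknown key is an explicit miss (``None``),
    never a silent empty path.
    """

    mapping: dict[str, OntologyPath] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, OntologyPath]) -> "OntologyLookup":
        return cls({k.strip(): v for k, v in pairs.items()})

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, key: str) -> bool:
        return key.strip() in self.mapping

    def resolve(self, key: str) -> Optional[OntologyPath]:
        """Resolve a structure key (SMILES/InChI) to its ontology path.

        Returns the stored path on a hit and ``None`` on a miss.  An
        empty/blank key is an input error: callers must not ask to resolve
        nothing.
        """
        if key is None or not str(key).strip():
            raise InputError("cannot resolve an empty structure key")
        return self.mapping.get(str(key).strip())


def resolve_structure(key: str, lookup: OntologyLookup) -> Optional[OntologyPath]:
    """Functional alias for :meth:`OntologyLookup.resolve`."""
    return lookup.resolve(key)
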