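"""Validation statistics for consensus-annotation runs.

Implements the validation procedure used to benchmark the tool: rerun the
engine with library matches withheld, compare the in-silico-derived
consensus labels against the withheld library identities to get a per-level
true positive rate; quantify how far consensus propagation expands the
annotation rate beyond library matches alone; and summarize per-sample
chemical-class abundance from feature intensities (XIC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io_gnps import ConsensusRow, NetworkAssignment
from .ontology import LEVELS, FeatureAnnotation, Source, dedupe_annotations

_ANNOTATED_LEVELS = frozenset(LEVELS)


@dataclass(frozen=True)
class LevelTPR:
    """TPR at one ontology level; ``tpr`` is None when nothing is evaluable."""

    n_evaluable: int
    n_match: int

    @property
    def tpr(self) -> Optional[float]:
        if self.n_evaluable == 0:
            return None
        return self.n_match / self.n_evaluable


@dataclass(frozen=True)
class TPRReport:
    """Per-level true positive rates plus their mean and spread.

    ``mean_tpr``/``sd_tpr`` aggregate across the hierarchy levels that are
    evaluable (sample standard deviation; None when fewer than two levels
    are defined).
    """

    levels: dict[str, LevelTPR]

    @property
    def mean_tpr(self) -> Optional[float]:
        vals = [lt.tpr for lt in self.levels.values() if lt.tpr is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def sd_tpr(self) -> Optional[float]:
        vals = [lt.tpr for lt in self.levels.values() if lt.tpr is not None]
        return float(np.std(vals, ddof=1)) if len(vals) >= 2 else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.levels),
                "n_evaluable": [lt.n_evaluable for lt in self.levels.values()],
                "n_match": [lt.n_match for lt in self.levels.values()],
                "tpr": [lt.tpr for lt in self.levels.values()],
            }
        )

    def to_text(self) -> str:
        lines = ["True positive rate (library truth vs consensus):"]
        for name, lt in self.levels.items():
            tpr = "undefined" if lt.tpr is None else f"{100 * lt.tpr:.2f}%"
            lines.append(
                f"  {name:<10} {tpr:>10}  ({lt.n_match}/{lt.n_evaluable} evaluable)"
            )
        if self.mean_tpr is not None:
            sd = "" if self.sd_tpr is None else f" ± {100 * self.sd_tpr:.2f}%"
            lines.append(f"  across levels: {100 * self.mean_tpr:.2f}%{sd}")
        return "\n".join(lines)


def compute_tpr(
    consensus_no_library: Sequence[ConsensusRow],
    library_truth: Iterable[FeatureAnnotation] | Mapping[int, FeatureAnnotation],
) -> TPRReport:
    """Per-level TPR of a no-library consensus run against withheld truth.

    A feature is evaluable at a level when BOTH its withheld library label
    and its consensus label at that level are non-empty; a match is
    case-insensitive label equality.  Levels with no evaluable feature are
    reported as undefined, never as 0 or 1.
    """
    truth = (
        dict(library_truth)
        if isinstance(library_truth, Mapping)
        else dedupe_annotations(library_truth)
    )
    counts = {name: [0, 0] for name in LEVELS}  # [evaluable, match]
    for row in consensus_no_library:
        ann = truth.get(row.feature_id)
        if ann is None:
            continue
        t_key = ann.path.key()
        c_key = row.path.key()
        for i, name in enumerate(LEVELS):
            if t_key[i] and c_key[i]:
                counts[name][0] += 1
                counts[name][1] += t_key[i] == c_key[i]
    return TPRReport({name: LevelTPR(ev, m) for name, (ev, m) in counts.items()})


@dataclass(frozen=True)
class CoverageReport:
    """Annotation-rate bookkeeping for one run.

    Rates follow the network-figure convention: singleton ("single-loop")
    nodes are excluded from the networked rates; all-feature variants are
    emitted alongside since published rates do not always say which was
    used.  ``expansion_percent`` is the percent increase of consensus-
    annotated networked features over library-annotated networked features
    (None when there are no library matches); ``expansion_ratio_percent``
    is the plain ratio ×100.
    """

    n_features: int
    n_networked: int
    n_library_annotated: int
    n_concise_annotated: int
    n_annotated_all: int
    annotation_rate: Optional[float]
    annotation_rate_all: Optional[float]
    expansion_percent: Optional[float]
    expansion_ratio_percent: Optional[float]

    def to_text(self) -> str:
        def pct(x: Optional[float]) -> str:
            return "undefined" if x is None else f"{100 * x:.1f}%"

        lines = [
            "Annotation coverage:",
            f"  features total / networked: {self.n_features} / {self.n_networked}",
            f"  library-annotated networked features: {self.n_library_annotated}",
            f"  consensus-annotated networked features: {self.n_concise_annotated}",
            f"  annotation rate (networked):  {pct(self.annotation_rate)}",
            f"  annotation rate (all feats):  {pct(self.annotation_rate_all)}",
        ]
        if self.expansion_percent is None:
            lines.append("  expansion over library matches: undefined (no matches)")
        else:
            lines.append(
                f"  expansion over library matches: {self.expansion_percent:.0f}%"
                f" (ratio {self.expansion_ratio_percent:.0f}%)"
            )
        return "\n".join(lines)


def compute_coverage(
    rows: Sequence[ConsensusRow],
    library_anns: Iterable[FeatureAnnotation] | Mapping[int, FeatureAnnotation],
    network: NetworkAssignment,
) -> CoverageReport:
    """Annotation rate and expansion of a consensus run.

    ``annotation_rate`` = fraction of networked (non-singleton) features
    whose consensus level is a real ontology level; ``expansion_percent``
    = 100 × (consensus-annotated − library-annotated) / library-annotated
    over the same networked features.
    """
    lib = (
        dict(library_anns)
        if isinstance(library_anns, Mapping)
        else dedupe_annotations(library_anns)
    )
    networked = {f for f in network.features if not network.is_singleton(f)}
    n_lib = sum(1 for f in networked if f in lib and lib[f].votes)
    annotated = {r.feature_id for r in rows if r.level in _ANNOTATED_LEVELS}
    n_con = len(annotated & networked)
    n_all = len(annotated)
    rate = n_con / len(networked) if networked else None
    rate_all = n_all / network.n_features if network.n_features else None
    if n_lib:
        expansion = 100.0 * (n_con - n_lib) / n_lib
        ratio = 100.0 * n_con / n_lib
    else:
        expansion = ratio = None
    return CoverageReport(
        n_features=network.n_features,
        n_networked=len(networked),
        n_library_annotated=n_lib,
        n_concise_annotated=n_con,
        n_annotated_all=n_all,
        annotation_rate=rate,
        annotation_rate_all=rate_all,
        expansion_percent=expansion,
        expansion_ratio_percent=ratio,
    )


def mean_consensus(rows: Sequence[ConsensusRow]) -> Optional[float]:
    """Mean consensus score (percent) over distinct annotated subnetworks.

    Each subnetwork is counted once, however many member features carry
    its score.  Requires engine-produced rows (which carry the component
    id in memory); singleton and unannotated rows have no score and are
    ignored.  Returns None when no subnetwork is annotated.
    """
    by_comp: dict[int, float] = {}
    for row in rows:
        if row.score is None or row.level not in _ANNOTATED_LEVELS:
            continue
        if row.component_id is None:
            raise InputError(
                "mean_consensus needs engine-produced rows carrying component ids"
            )
        by_comp[row.component_id] = row.score
    if not by_comp:
        return None
    return float(np.mean(list(by_comp.values())))


def class_abundance(
    rows: Sequence[ConsensusRow], feature_intensities: pd.DataFrame
) -> pd.DataFrame:
    """Percent of classified signal per superclass, per sample.

    ``feature_intensities`` is a features×samples table (index =
    feature_id).  For each sample, the intensity of features with a real
    consensus level is summed by consensus superclass and normalized to
    100%; unclassified features never enter the denominator.  Samples with
    zero classified signal come back as NaN (undefined).
    """
    superclass_of = {
        r.feature_id: r.path.superclass
        for r in rows
        if r.level in _ANNOTATED_LEVELS and r.path.superclass
    }
    classified = feature_intensities.loc[
        feature_intensities.index.intersection(list(superclass_of))
    ]
    if classified.empty:
        return pd.DataFrame(
            index=feature_intensities.columns, dtype=float
        ).rename_axis("sample")
    groups = classified.groupby(
        [superclass_of[f] for f in classified.index]
    ).sum()  # superclass × sample
    totals = groups.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * groups.div(totals.where(totals > 0), axis=1)
    out = percent.T.rename_axis("sample")
    out.columns.name = "superclass"
    return out
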