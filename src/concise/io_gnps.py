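"""Readers and writers for the GNPS/SIRIUS table dialects.

Three inputs drive a run: the networking table (GNPS
``clusterinfo_summary`` dialect: ``cluster index`` / ``componentindex``
columns), the in silico class-prediction table (either a generic
``featureNumber``/``superclass``/``class``/``subclass`` TSV or the CANOPUS
summary exported by SIRIUS), and a library-match table (local TSV or a
table fetched from a GNPS task).  The single output is
``ConCISEConsensus.csv`` with one row per networked feature.

All tables are tab-separated UTF-8 with a header row; the output is CSV.
File I/O lives here only — the consensus engine is pure in-memory.
"""

from __future__ import annotations

import logging
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .errors import InputError, SchemaError, TransportError
from .ontology import (
    LEVELS,
    FeatureAnnotation,
    OntologyLookup,
    OntologyPath,
    Source,
    dedupe_annotations,
    make_path,
    normalize_label,
)

logger = logging.getLogger(__name__)

SINGLETON_SENTINEL = -1

CONSENSUS_FILENAME = "ConCISEConsensus.csv"

#: Output schema of ConCISEConsensus.csv, in order.
CONSENSUS_COLUMNS = (
    "feature_id",
    "superclass",
    "class",
    "subclass",
    "score",
    "level",
    "n_nodes",
    "source",
)


# ---------------------------------------------------------------------------
# containers


@dataclass
class NetworkAssignment:
    """Feature -> subnetwork (connected component) map.

    ``component_of[feature_id] == singleton_sentinel`` marks singleton
    nodes (features with no network neighbors); every other component id
    groups at least two features.
    """

    component_of: dict[int, int]
    singleton_sentinel: int = SINGLETON_SENTINEL

    @property
    def features(self) -> list[int]:
        return sorted(self.component_of)

    @property
    def n_features(self) -> int:
        return len(self.component_of)

    def is_singleton(self, feature_id: int) -> bool:
        return self.component_of[feature_id] == self.singleton_sentinel

    @property
    def singletons(self) -> list[int]:
        return [f for f in self.features if self.is_singleton(f)]

    def components(self) -> dict[int, list[int]]:
        """Component id -> sorted member features (singletons excluded)."""
        out: dict[int, list[int]] = {}
        for fid in self.features:
            comp = self.component_of[fid]
            if comp != self.singleton_sentinel:
                out.setdefault(comp, []).append(fid)
        return out


@dataclass
class ConsensusRow:
    """One output row: a feature and the annotation propagated to it.

    ``level`` is the deepest ontology level at which consensus was reached
    (``superclass``/``class``/``subclass``), or ``no_consensus`` when the
    subnetwork's votes disagreed at superclass, or ``none`` when nothing
    voted at all.  ``score`` is the percent consensus at ``level`` (empty
    for singletons and unannotated rows).  ``component_id`` is in-memory
    bookkeeping only and is not serialized.
    """

    feature_id: int
    path: OntologyPath = field(default_factory=OntologyPath)
    score: Optional[float] = None
    level: str = "none"
    n_nodes: int = 0
    source: Source = Source.NONE
    component_id: Optional[int] = None

    def csv_record(self) -> dict[str, object]:
        return {
            "feature_id": self.feature_id,
            "superclass": self.path.superclass,
            "class": self.path.class_,
            "subclass": self.path.subclass,
            "score": "" if self.score is None else f"{self.score:.2f}",
            "level": self.level,
            "n_nodes": self.n_nodes,
            "source": self.source.value,
        }


# ---------------------------------------------------------------------------
# helpers


def _read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _find_column(columns: Sequence[str], candidates: Iterable[str]) -> Optional[str]:
    """First column whose casefolded name matches any candidate."""
    by_fold = {c.casefold(): c for c in reversed(list(columns))}
    for cand in candidates:
        hit = by_fold.get(cand.casefold())
        if hit is not None:
            return hit
    return None


def _parse_feature_id(raw: str, context: str) -> int:
    """Parse a feature id; GNPS cluster indices are integral.

    SIRIUS id columns embed the feature number at the end of a longer
    string (e.g. ``report_mzML_12``); a trailing integer is accepted.
    """
    text = str(raw).strip()
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return int(float(text))  # "12.0"
    except ValueError:
        pass
    m = re.search(r"(\d+)\s*$", text)
    if m:
        return int(m.group(1))
    raise SchemaError(f"{context}: cannot parse feature id from {raw!r}")


# ---------------------------------------------------------------------------
# readers


def read_network_info(path: Path | str) -> NetworkAssignment:
    """Read the networking table (clusterinfo_summary dialect).

    Requires ``cluster index`` and ``componentindex`` columns; extra
    columns are ignored.  GNPS marks singletons with componentindex −1;
    defensively, a "component" of size 1 with any other id is reclassified
    as a singleton with a warning.
    """
    df = _read_tsv(path)
    cluster_col = _find_column(df.columns, ["cluster index"])
    comp_col = _find_column(df.columns, ["componentindex"])
    for name, col in (("cluster index", cluster_col), ("componentindex", comp_col)):
        if col is None:
            raise SchemaError(f"networking table is missing required column {name!r}")

    component_of: dict[int, int] = {}
    for raw_fid, raw_comp in zip(df[cluster_col], df[comp_col]):
        fid = _parse_feature_id(raw_fid, "networking table")
        if fid in component_of:
            raise SchemaError(f"duplicate feature id {fid} in networking table")
        try:
            comp = int(float(str(raw_comp).strip()))
        except ValueError as exc:
            raise SchemaError(
                f"networking table: bad componentindex {raw_comp!r} for feature {fid}"
            ) from exc
        component_of[fid] = comp

    assignment = NetworkAssignment(component_of)
    # reclassify size-1 "components"
    sizes: dict[int, int] = {}
    for comp in component_of.values():
        if comp != assignment.singleton_sentinel:
            sizes[comp] = sizes.get(comp, 0) + 1
    lonely = {c for c, n in sizes.items() if n == 1}
    if lonely:
        logger.warning(
            "%d component id(s) contain a single feature; treating as singletons",
            len(lonely),
        )
        for fid, comp in component_of.items():
            if comp in lonely:
                component_of[fid] = assignment.singleton_sentinel
    logger.info(
        "networking table: %d features, %d subnetworks, %d singletons",
        assignment.n_features,
        len(assignment.components()),
        len(assignment.singletons),
    )
    return assignment


_GENERIC_COLS = ("featureNumber", "superclass", "class", "subclass")
_SIRIUS_ID_CANDIDATES = ("mappingFeatureId", "featureId", "id", "name")


def read_canopus_summary(path: Path | str) -> list[FeatureAnnotation]:
    """Read the in silico class-prediction table (source=in_silico).

    Two dialects are detected by header sniffing:

    * generic — columns ``featureNumber``, ``superclass``, ``class``,
      ``subclass`` (any in silico tool with a three-level ontology);
    * SIRIUS CANOPUS export — feature id embedded in an id column and the
      ClassyFire levels as ``ClassyFire#superclass`` etc.

    One annotation per feature is returned (duplicates keep the most
    complete path, ties to first occurrence); paths are normalized and
    prefix-closed.
    """
    df = _read_tsv(path)
    cols = list(df.columns)

    generic = {c.casefold(): c for c in cols}
    if all(c.casefold() in generic for c in _GENERIC_COLS):
        id_col = generic["featurenumber"]
        level_cols = [generic[l] for l in ("superclass", "class", "subclass")]
    else:
        level_cols_opt = [
            _find_column(cols, [f"ClassyFire#{lvl}"]) for lvl in LEVELS
        ]
        id_col_opt = _find_column(cols, _SIRIUS_ID_CANDIDATES)
        if id_col_opt is None or any(c is None for c in level_cols_opt):
            raise SchemaError(
                "in silico table matches neither the generic "
                "(featureNumber/superclass/class/subclass) nor the SIRIUS "
                f"CANOPUS dialect; found headers: {cols}"
            )
        id_col = id_col_opt
        level_cols = [c for c in level_cols_opt if c is not None]

    anns: list[FeatureAnnotation] = []
    n_repaired = 0
    for _, row in df.iterrows():
        fid = _parse_feature_id(row[id_col], "in silico table")
        path, repaired = make_path(*(row[c] for c in level_cols))
        n_repaired += repaired
        anns.append(FeatureAnnotation(fid, Source.IN_SILICO, path))
    if n_repaired:
        logger.warning(
            "in silico table: repaired %d row(s) violating prefix closure", n_repaired
        )
    deduped = dedupe_annotations(anns)
    logger.info("in silico table: %d annotated features", len(deduped))
    return [deduped[fid] for fid in sorted(deduped)]


_LIBRARY_ID_CANDIDATES = ("#Scan#", "featureNumber", "cluster index", "feature_id", "scan")
_STRUCTURE_CANDIDATES = ("Smiles", "INCHI", "InChI", "structure_key")
_NAME_CANDIDATES = ("Compound_Name", "compound_name")


def read_library_table(
    path: Path | str, lookup: Optional[OntologyLookup] = None
) -> list[FeatureAnnotation]:
    """Read the spectral-library match table (source=library).

    Explicit ``superclass``/``class``/``subclass`` columns win when
    present (GNPS exports often include ClassyFire fields); otherwise the
    structure key (SMILES/InChI) is resolved through ``lookup``.  Matches
    lacking both ontology labels and a resolvable structure are excluded
    from voting, with a logged count.
    """
    df = _read_tsv(path)
    cols = list(df.columns)
    id_col = _find_column(cols, _LIBRARY_ID_CANDIDATES)
    if id_col is None:
        raise SchemaError(
            f"library table has no feature-id column (looked for any of "
            f"{_LIBRARY_ID_CANDIDATES}); found headers: {cols}"
        )
    level_cols = [_find_column(cols, [lvl]) for lvl in LEVELS]
    has_labels = all(c is not None for c in level_cols)
    struct_col = _find_column(cols, _STRUCTURE_CANDIDATES)
    name_col = _find_column(cols, _NAME_CANDIDATES)

    anns: list[FeatureAnnotation] = []
    n_dropped = 0
    for _, row in df.iterrows():
        fid = _parse_feature_id(row[id_col], "library table")
        structure = normalize_label(row[struct_col]) if struct_col else ""
        name = str(row[name_col]).strip() if name_col else None
        path = None
        if has_labels:
            cand, _ = make_path(*(row[c] for c in level_cols))  # type: ignore[arg-type]
            if not cand.is_empty:
                path = cand
        if path is None and structure and lookup is not None:
            path = lookup.resolve(structure)
        if path is None or path.is_empty:
            n_dropped += 1
            continue
        anns.append(
            FeatureAnnotation(
                fid,
                Source.LIBRARY,
                path,
                structure_key=structure or None,
                compound_name=name or None,
            )
        )
    if n_dropped:
        logger.info(
            "library table: %d match(es) without labels or a resolvable "
            "structure excluded from voting",
            n_dropped,
        )
    deduped = dedupe_annotations(anns)
    logger.info("library table: %d voting-eligible library annotations", len(deduped))
    return [deduped[fid] for fid in sorted(deduped)]


def read_ontology_lookup(path: Path | str) -> OntologyLookup:
    """Read the local structure-key lookup.

    Four-column TSV with header
    ``structure_key<TAB>superclass<TAB>class<TAB>subclass``.
    """
    df = _read_tsv(path)
    required = ("structure_key", *LEVELS)
    by_fold = {c.casefold(): c for c in df.columns}
    missing = [c for c in required if c.casefold() not in by_fold]
    if missing:
        raise SchemaError(f"ontology lookup is missing column(s) {missing}")
    mapping: dict[str, OntologyPath] = {}
    for _, row in df.iterrows():
        key = str(row[by_fold["structure_key"]]).strip()
        if not key:
            continue
        path, _ = make_path(*(row[by_fold[l.casefold()]] for l in LEVELS))
        if key in mapping and mapping[key] != path:
            raise SchemaError(f"ontology lookup maps key {key!r} to two paths")
        mapping[key] = path
    return OntologyLookup(mapping)


# ---------------------------------------------------------------------------
# GNPS task fetcher

_TASK_ID_RE = re.compile(r"[0-9a-fA-F]{32}")

#: Assumed endpoint for a networking job's library-match table.  The exact
#: GNPS REST shape varies across workflow releases; the transport is
#: injectable so tests (and alternate deployments) never depend on it.
GNPS_DB_RESULT_URL = (
    "https://gnps.ucsd.edu/ProteoSAFe/DownloadResultFile"
    "?task={task_id}&file=DB_result/&block=main"
)


def _default_transport(url: str) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            return resp.read()
    except Exception as exc:  # URLError, HTTPError, timeout
        raise TransportError(f"GNPS fetch failed: {exc}") from exc


def fetch_gnps_task(
    task_id: str,
    cache_dir: Path | str = ".concise_cache",
    transport: Optional[Callable[[str], bytes]] = None,
) -> Path:
    """Fetch (and cache) the library-match table of a GNPS networking job.

    ``task_id`` must be a 32-hex-character GNPS task identifier; it is
    validated before any request.  Raw responses are cached under
    ``cache_dir`` keyed by task id, so a repeat call returns the identical
    bytes with no network traffic.  Returns the path to the cached TSV,
    which ``read_library_table`` accepts.
    """
    if not _TASK_ID_RE.fullmatch(task_id or ""):
        raise InputError(
            f"malformed GNPS task id {task_id!r}: expected 32 hex characters"
        )
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{task_id.lower()}.tsv"
    if target.exists():
        logger.info("GNPS task %s: cache hit", task_id)
        return target
    url = GNPS_DB_RESULT_URL.format(task_id=task_id)
    payload = (transport or _default_transport)(url)
    target.write_bytes(payload)
    logger.info("GNPS task %s: fetched %d bytes", task_id, len(payload))
    return target


# ---------------------------------------------------------------------------
# writer


def write_consensus_csv(rows: Iterable[ConsensusRow], out_dir: Path | str) -> Path:
    """Write ``ConCISEConsensus.csv`` (UTF-8, header row).

    One row per feature, ordered by feature id ascending; scores carry two
    decimal places (full precision stays in memory).
    """
    out = Path(out_dir) / CONSENSUS_FILENAME
    ordered = sorted(rows, key=lambda r: r.feature_id)
    df = pd.DataFrame(
        [r.csv_record() for r in ordered], columns=list(CONSENSUS_COLUMNS)
    )
    try:
        df.to_csv(out, index=False, lineterminator="\n")
    except OSError as exc:
        raise InputError(f"cannot write {out}: {exc}") from exc
    return out


def read_consensus_csv(path: Path | str) -> list[ConsensusRow]:
    """Re-read a ``ConCISEConsensus.csv`` into :class:`ConsensusRow` objects.

    Inverse of :func:`write_consensus_csv` up to the serialized score
    precision; ``component_id`` is not stored and reads back as ``None``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CONSENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"consensus csv is missing column(s) {missing}")
    rows: list[ConsensusRow] = []
    for _, rec in df.iterrows():
        score = float(rec["score"]) if rec["score"] != "" else None
        rows.append(
            ConsensusRow(
                feature_id=int(rec["feature_id"]),
                path=OntologyPath(rec["superclass"], rec["class"], rec["subclass"]),
                score=score,
                level=rec["level"],
                n_nodes=int(rec["n_nodes"]),
                source=Source(rec["source"]),
            )
        )
    return rows
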