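"""Consensus voting, level selection, singleton rule and propagation."""

import numpy as np
import pytest

from conftest import brute_force_consensus, random_paths

from concise.engine import (
    ConsensusConfig,
    derive_consensus,
    handle_singleton,
    propagate,
    run_concise,
    select_source,
    vote_level,
)
from concise.errors import ConsistencyError, InputError
from concise.io_gnps import NetworkAssignment
from concise.ontology import FeatureAnnotation, OntologyPath, Source


def P(*labels):
    return OntologyPath(*(list(labels) + [""] * (3 - len(labels))))


def ann(fid, source, *labels):
    return FeatureAnnotation(fid, source, P(*labels))


# ---------------------------------------------------------------------------
# config


def test_config_validates_thresholds_and_mode():
    with pytest.raises(InputError):
        ConsensusConfig(t_superclass=0.0)
    with pytest.raises(InputError):
        ConsensusConfig(t_class=1.5)
    with pytest.raises(InputError):
        ConsensusConfig(threshold_mode="sometimes")
    # independent overrides are legal: no ordering constraint between levels
    ConsensusConfig(t_superclass=0.9, t_class=0.2, t_subclass=0.6)


# ---------------------------------------------------------------------------
# source selection (library outranks in silico)


def test_select_source_hierarchy():
    lib = {1: ann(1, Source.LIBRARY, "A")}
    sil = {f: ann(f, Source.IN_SILICO, "B") for f in range(1, 11)}
    assert select_source(range(1, 11), lib, sil) is Source.LIBRARY
    assert select_source(range(1, 11), {}, sil) is Source.IN_SILICO
    assert select_source(range(1, 11), {}, {}) is Source.NONE
    # an empty-path library record is not voting-eligible
    assert select_source([1], {1: ann(1, Source.LIBRARY)}, {}) is Source.NONE


# ---------------------------------------------------------------------------
# voting


def test_vote_level_majority_and_fraction():
    paths = [P("Organic acids and derivatives")] * 6 + [P("Benzenoids")] * 4
    winner, frac = vote_level(paths, 0)
    assert winner == "Organic acids and derivatives"
    assert frac == pytest.approx(0.6)


def test_vote_level_denominator_counts_blank_labels():
    # 7/10 share the class; 2 blanks still count against consensus
    paths = [P("S", "C")] * 7 + [P("S")] * 2 + [P("S", "D")]
    winner, frac = vote_level(paths, 1, required_prefix=("s",))
    assert winner == "C" and frac == pytest.approx(0.7)


def test_vote_level_tie_returns_no_winner():
    paths = [P("A")] * 2 + [P("B")] * 2
    winner, frac = vote_level(paths, 0)
    assert winner is None and frac == pytest.approx(0.5)


def test_vote_level_requires_paths():
    with pytest.raises(InputError):
        vote_level([], 0)


# ---------------------------------------------------------------------------
# level selection


def cfg(**kw):
    return ConsensusConfig(**kw)


def test_unanimous_paths_reach_subclass_at_100():
    paths = [P("S", "C", "U")] * 43
    res = derive_consensus(131, paths, cfg(), Source.IN_SILICO)
    assert res.level == "subclass"
    assert res.score == pytest.approx(100.0)
    assert res.n_nodes == 43
    assert res.path.labels() == ("S", "C", "U")


def test_stops_at_class_when_subclass_vote_fails():
    # 6/10 superclass S… but nested: 7/10 share (S, C); 5/10 share (S, C, U)
    paths = (
        [P("S", "C", "U")] * 5
        + [P("S", "C", "V")] * 2
        + [P("S", "D", "U")] * 1
        + [P("T", "C", "U")] * 2
    )
    res = derive_consensus(1, paths, cfg(), Source.IN_SILICO)
    assert res.level == "class"
    assert res.path.labels() == ("S", "C", "")
    assert res.score == pytest.approx(70.0)


def test_no_consensus_when_superclass_below_threshold():
    paths = [P("S")] * 4 + [P("T")] * 3 + [P("U")] * 2 + [P("V")]
    res = derive_consensus(1, paths, cfg(), Source.IN_SILICO)
    assert res.level == "no_consensus"
    assert res.path.is_empty and res.score is None


def test_at_least_vs_strictly_greater_boundary():
    paths = [P("S")] * 5 + [P("T")] * 3 + [P("U")] * 2
    assert derive_consensus(1, paths, cfg(), Source.IN_SILICO).level == "superclass"
    strict = cfg(threshold_mode="strictly_greater")
    assert derive_consensus(1, paths, strict, Source.IN_SILICO).level == "no_consensus"


def test_deeper_vote_constrained_to_extend_winner():
    # label "A" appears at class level in 9/10 paths, but only 6 of those
    # sit under the winning superclass S: the nested vote counts prefixes,
    # not bare labels, so the class vote fails (6/10 < 0.70)
    paths = [P("S", "A")] * 6 + [P("S", "B")] * 1 + [P("T", "A")] * 3
    res = derive_consensus(1, paths, cfg(), Source.IN_SILICO)
    assert res.path.superclass == "S"
    assert res.level == "superclass" and res.path.class_ == ""


# ---------------------------------------------------------------------------
# oracle equivalence on random small components


@pytest.mark.parametrize("seed", range(10))
def test_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    config = cfg()
    for _ in range(100):
        n = int(rng.integers(1, 7))
        paths = random_paths(rng, n)
        if not any(p.superclass for p in paths):
            continue
        res = derive_consensus(0, paths, config, Source.IN_SILICO)
        level, labels, score = brute_force_consensus(paths, config)
        assert res.level == level
        got = tuple(l for l in res.path.labels() if l)
        assert got == labels
        if score is None:
            assert res.score is None
        else:
            assert res.score == pytest.approx(score)


# ---------------------------------------------------------------------------
# singleton rule


def test_singleton_gets_its_library_annotation_only():
    lib = {4: ann(4, Source.LIBRARY, "S", "C", "U")}
    row = handle_singleton(4, lib)
    assert row.source is Source.LIBRARY
    assert row.level == "subclass" and row.n_nodes == 1
    assert row.score is None
    assert row.path.labels() == ("S", "C", "U")


def test_singleton_never_receives_in_silico():
    row = handle_singleton(4, {})  # in silico exists elsewhere, not passed here
    assert row.source is Source.NONE and row.level == "none"
    assert row.path.is_empty


def test_singleton_partial_library_path_sets_level():
    lib = {4: ann(4, Source.LIBRARY, "S")}
    assert handle_singleton(4, lib).level == "superclass"


# ---------------------------------------------------------------------------
# propagation


def _net(component_of):
    return NetworkAssignment(dict(component_of))


def test_propagation_reaches_unannotated_members():
    net = _net({f: 1 for f in range(1, 13)})
    sil = [ann(f, Source.IN_SILICO, "S", "C") for f in range(1, 6)]
    rows = run_concise(net, [], sil)
    assert len(rows) == 12
    assert all(r.level == "class" and r.path.class_ == "C" for r in rows)
    assert all(r.n_nodes == 5 for r in rows)


def test_no_consensus_propagates_empty_labels():
    net = _net({1: 1, 2: 1, 3: 1, 4: 1})
    sil = [
        ann(1, Source.IN_SILICO, "A"),
        ann(2, Source.IN_SILICO, "B"),
        ann(3, Source.IN_SILICO, "C"),
        ann(4, Source.IN_SILICO, "D"),
    ]
    rows = run_concise(net, [], sil)
    assert all(r.level == "no_consensus" and r.path.is_empty for r in rows)
    assert all(r.score is None for r in rows)


def test_unannotated_component_is_none_not_no_consensus():
    net = _net({1: 1, 2: 1})
    rows = run_concise(net, [], [])
    assert all(r.level == "none" and r.source is Source.NONE for r in rows)


def test_propagate_rejects_unknown_component():
    from concise.engine import ConsensusResult

    net = _net({1: 1, 2: 1})
    ghost = ConsensusResult(99, "superclass", P("S"), 100.0, 1, Source.IN_SILICO)
    with pytest.raises(ConsistencyError):
        propagate(net, {99: ghost}, {})


def test_library_outranks_in_silico_and_no_default_fallback():
    # library votes disagree -> no consensus; in silico is unanimous but
    # must NOT be used unless fallback is opted in
    net = _net({f: 1 for f in range(1, 5)})
    lib = [ann(1, Source.LIBRARY, "A"), ann(2, Source.LIBRARY, "B")]
    sil = [ann(f, Source.IN_SILICO, "S", "C", "U") for f in range(1, 5)]
    rows = run_concise(net, lib, sil)
    assert all(r.level == "no_consensus" and r.source is Source.LIBRARY for r in rows)

    rows_fb = run_concise(net, lib, sil, ConsensusConfig(fallback_to_insilico=True))
    assert all(r.level == "subclass" and r.source is Source.IN_SILICO for r in rows_fb)


def test_empty_insilico_equals_library_only_run():
    net = _net({f: 1 for f in range(1, 4)})
    lib = [ann(f, Source.LIBRARY, "S", "C") for f in range(1, 3)]
    a = run_concise(net, lib, [])
    b = run_concise(net, lib, [ann(3, Source.IN_SILICO, "X")] * 0)
    assert a == b


def test_mixed_network_row_count_and_singleton_sources(small_bundle):
    b = small_bundle
    rows = run_concise(b.network, b.library_annotations, b.insilico_annotations)
    assert len(rows) == b.network.n_features
    singles = set(b.network.singletons)
    for r in rows:
        if r.feature_id in singles:
            assert r.source in (Source.LIBRARY, Source.NONE)
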