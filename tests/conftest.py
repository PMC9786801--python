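"""Shared fixtures and the independent brute-force consensus oracle."""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pytest

from concise.engine import ConsensusConfig
from concise.fixtures import FixtureSpec, generate_network, generate_ontology
from concise.ontology import LEVELS, OntologyPath


def brute_force_consensus(
    paths: Sequence[OntologyPath], config: ConsensusConfig
) -> tuple[str, tuple[str, ...], Optional[float]]:
    """Independent oracle: enumerate every candidate prefix at every level
    and apply the cutoffs literally.

    For each level, every distinct non-empty label prefix of that length
    is a candidate; a candidate is accepted when it is the unique most
    frequent prefix extending the accepted shallower prefix AND its
    frequency over all voting paths passes that level's cutoff.  Returns
    ``(level_name_or_no_consensus, accepted display labels, score)``.
    Deliberately naive — no shared code with the engine.
    """
    n = len(paths)
    accepted: tuple[str, ...] = ()
    accepted_display: tuple[str, ...] = ()
    score = None
    level_name = "no_consensus"
    for depth in range(3):
        counter: Counter[tuple[str, ...]] = Counter()
        display: dict[tuple[str, ...], str] = {}
        for p in paths:
            key = p.key()
            cand = key[: depth + 1]
            if key[:depth] == accepted and cand[depth] != "":
                counter[cand] += 1
                display.setdefault(cand, p.label_at(depth))
        if not counter:
            break
        top = max(counter.values())
        winners = [c for c, k in counter.items() if k == top]
        frac = top / n
        threshold = config.thresholds[depth]
        passes = frac >= threshold if config.threshold_mode == "at_least" else frac > threshold
        if len(winners) != 1 or not passes:
            break
        accepted = winners[0]
        accepted_display = accepted_display + (display[accepted],)
        score = 100.0 * frac
        level_name = LEVELS[depth]
    return level_name, accepted_display, score


def random_paths(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int, int] = (3, 2, 2),
    p_blank: float = 0.15,
) -> list[OntologyPath]:
    """Random voting paths over a small vocabulary, with random truncation
    so empty-label handling gets exercised."""
    _, vocab = generate_ontology(shape)
    full = vocab.full_paths()
    out = []
    for _ in range(n):
        p = full[rng.integers(len(full))]
        r = rng.random()
        if r < p_blank:
            p = p.truncate(int(rng.integers(0, 3)))
        out.append(p)
    return out


@pytest.fixture(scope="session")
def small_bundle():
    """A modest planted study shared across read-only tests."""
    return generate_network(FixtureSpec(seed=7))


@pytest.fixture()
def tiny_vocab():
    lookup, vocab = generate_ontology((2, 2, 2))
    return lookup, vocab
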