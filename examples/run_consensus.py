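"""Derive and propagate consensus annotations for a molecular network.

Builds a small synthetic study (a networking table, an in silico
class-prediction table and a library-match table with a structure-key
lookup), writes it to disk in the GNPS/SIRIUS dialects, re-reads it
through the parsers, runs the consensus engine at the shipped 50/70/70
cutoffs, and writes ConCISEConsensus.csv.
"""

import tempfile
from pathlib import Path

from concise import (
    ConsensusConfig,
    compute_coverage,
    mean_consensus,
    read_canopus_summary,
    read_library_table,
    read_network_info,
    read_ontology_lookup,
    run_concise,
    write_consensus_csv,
)
from concise.fixtures import FixtureSpec, generate_network, write_fixture_dir

workdir = Path(tempfile.mkdtemp(prefix="concise-example-"))
fixture = write_fixture_dir(
    generate_network(FixtureSpec(n_components=25, n_singletons=8, seed=42)),
    workdir / "inputs",
)

network = read_network_info(fixture / "network_info.tsv")
insilico = read_canopus_summary(fixture / "canopus_summary.tsv")
lookup = read_ontology_lookup(fixture / "ontology_lookup.tsv")
library = read_library_table(fixture / "library_matches.tsv", lookup)

rows = run_concise(network, library, insilico, ConsensusConfig())
csv_path = write_consensus_csv(rows, workdir)

print(f"wrote {csv_path}")
print(compute_coverage(rows, library, network).to_text())
print(f"Mean subnetwork consensus: {mean_consensus(rows):.1f}%")
print()
print("First rows (feature, propagated path, score, level, source):")
for r in rows[:5]:
    labels = " > ".join(l for l in r.path.labels() if l) or "-"
    score = "-" if r.score is None else f"{r.score:.1f}%"
    print(f"  {r.feature_id:>4}  {labels:<24} {score:>7}  {r.level:<12} {r.source.value}")

# Every feature of a subnetwork carries the subnetwork's consensus path
# (propagation), at the deepest ontology level whose vote cleared its
# cutoff; the score is the percent of annotated nodes agreeing there.
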