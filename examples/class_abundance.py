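"""Summarize per-sample chemical-class abundance from consensus labels.

After consensus propagation, each classified feature carries a superclass;
weighting by per-sample feature intensity (XIC area) gives the percent of
classified signal in each chemical superclass per sample — the standard
stacked-bar view of sample chemo-diversity.
"""

from concise import class_abundance, run_concise
from concise.fixtures import FixtureSpec, generate_network, random_intensities

bundle = generate_network(FixtureSpec(n_components=30, seed=7))
rows = run_concise(
    bundle.network, bundle.library_annotations, bundle.insilico_annotations
)
intensities = random_intensities(bundle, n_samples=3, seed=7)

table = class_abundance(rows, intensities)
print("Percent of classified signal per superclass (columns sum to 100 per sample):")
print(table.round(1).to_string())
print(f"\nrow sums: {table.sum(axis=1).round(6).tolist()}")
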