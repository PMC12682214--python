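"""Score a pool of species on the target-suitability framework.

Loads the bundled Medan trait table, computes every framework variable per
species, and assembles the complete score matrix, reporting which variables
had to be dropped for lack of data.
"""

from capturedkit import build_score_matrix, load_medan_fixture, score_species

fixture = load_medan_fixture()
profiles = [score_species(t, abundance_mode="medan_compat") for t in fixture.traits]
matrix = build_score_matrix(profiles)

print(matrix.to_dataframe().to_string())
print()
for name, reason in matrix.dropped_variables:
    print(f"dropped {name}: {reason}")
print()
print(
    f"{len(matrix.species)} species x {len(matrix.variables)} variables. "
    "Higher scores mean the species is easier to obtain (supply side) or "
    "more attractive to buyers (demand side); each column keeps its own "
    "ordinal scale."
)
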