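"""Explain observed market counts with a principal component regression.

Runs the full pipeline on the bundled Medan worked example: standardize the
10 x 12 score matrix, PCA, orient PC1 positively with the counts, and
regress counts on the first two component scores.
"""

from capturedkit import analyze, build_score_matrix, load_medan_fixture, score_species

fixture = load_medan_fixture()
matrix = build_score_matrix(
    [score_species(t, abundance_mode="medan_compat") for t in fixture.traits]
)
report = analyze(matrix, fixture.counts, k=2, pca_mode="correlation")

print(report.summary_text())
print()
pc1 = {v: c["PC1"] for v, c in report.correlations.to_dict().items()}
print("Strongest variable-PC1 associations (|r| > 0.5):")
for var, r in sorted(pc1.items(), key=lambda kv: -abs(kv[1])):
    if abs(r) > 0.5:
        print(f"  {var:<22} r = {r:+.2f}")
print()
print(
    "PC1 separates heavily traded, abundant, accessible species from rare "
    "protected ones; its positive regression coefficient means species "
    "scoring high on that axis were detected in larger numbers in the "
    "markets."
)
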