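"""Stability diagnostics: 10-fold local/global analysis and energy landscape.

The k-fold analysis rebuilds the cost function on each fold's subset,
solves it locally, and scores the fold's selection against the full-data
selection; the landscape enumerates all 1,140 three-feature combinations
of the top 20 ranked features under one global cost function.
"""

from qubofs import (
    kfold_stability,
    landscape_enumeration,
    make_benchmark,
    select_features,
)

data = make_benchmark(seed=0, p=4000)

report = kfold_stability(data.X, data.y, k_features=5, n_folds=10, seed=0)
print(report.to_frame().to_string(index=False))
print(
    f"mean fold accuracy {report.mean_accuracy:.1f}%  "
    f"(min {report.min_accuracy:.1f}%)"
)
# accuracy = overlap of each fold's top-5 with the full-data top-5.

result = select_features(data.X, data.y, k=5, seed=0)
top20 = [int(i) for i in result.ranking[:20]]
landscape = landscape_enumeration(result.qubo, top20, 3)
print(f"\n{len(landscape)} combinations of 3 from the top 20")
print("lowest-energy triples:")
print(landscape.nsmallest(3, "energy").to_string(index=False))
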