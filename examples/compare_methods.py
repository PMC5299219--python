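"""GA vs GWO vs IGWO under the repeated cross-validation protocol.

Each method selects features and is scored by stratified 10-fold CV repeated
3 times (the benchmark protocol uses 10 repeats; 3 keeps this example quick).
Each row gives mean +/- sd percentages over repeats for the six
confusion-matrix metrics and the mean number of selected features — the
layout of the benchmark comparison tables.
"""

from wolfsel import SyntheticSpec, evaluate_method, generate_synthetic
from wolfsel.evaluation import METRIC_NAMES

data = generate_synthetic(SyntheticSpec(
    n_samples=100, n_informative=5, n_noise=15, class_separation=2.0, seed=5))

header = f"{'method':6s} {'size':>11s} " + " ".join(f"{m:>15s}" for m in METRIC_NAMES)
print(header)
for mode in ("GA", "GWO", "IGWO"):
    res = evaluate_method(data, mode=mode, pop_size=8, iterations=100,
                          k=10, repeats=3, seed=1)
    row = res.report.format_row()
    print(f"{mode:6s} {row['features_size']:>11s} "
          + " ".join(f"{row[m]:>15s}" for m in METRIC_NAMES))
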