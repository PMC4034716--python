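"""Comparing the weighted and positional voting measures by 1NN error.

Runs repeated stratified 10-fold cross-validation of both measures on a
moderately separated synthetic dataset and compares their per-repeat error
rates with the Wilcoxon signed-rank test.
"""

from wborda import (
    SearchConfig,
    SyntheticSpec,
    cross_validate,
    generate_labeled_mts,
    wilcoxon_signed_rank,
)

dataset = generate_labeled_mts(
    SyntheticSpec(
        n_classes=3, items_per_class=12, m=40, n=5,
        latent_rank=2, separation=1.2, noise_sd=0.4, seed=3,
    )
)

reports = {}
for measure in ("wborda", "borda"):
    reports[measure] = cross_validate(
        dataset, SearchConfig(measure=measure), folds=10, repeats=10, seed=3
    )
    print(
        f"{measure:7s}: mean 1NN error {reports[measure].mean_error:.1f}%  "
        f"(p = {set(reports[measure].p_used)} components retained)"
    )

test = wilcoxon_signed_rank(
    reports["borda"].repeat_means, reports["wborda"].repeat_means
)
print(
    f"Wilcoxon signed-rank on the {test.n_nonzero} nonzero paired repeats: "
    f"W+ = {test.w_plus}, z = {test.z:.3f}, two-sided p = {test.p_value:.3f}"
)
# A small p with W+ below its null mean indicates the weighted measure's
# per-repeat errors are systematically lower than the positional baseline's.
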