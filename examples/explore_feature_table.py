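"""Load, normalize, filter, cluster and render a feature table.

Builds a synthetic amplicon study, applies the standard preprocessing
(total-sum scaling to 10 000 reads/sample, dropping features with fewer
than 10 normalized reads overall), orders features by clustering, and
writes a self-contained HTML heatmap.
"""

import abundex as ax

exp, _ = ax.make_count_experiment(n_per_group=(12, 12), n_features=80, seed=11)
print("raw:", exp)

exp = ax.normalize_tss(exp, total=10_000)
exp = ax.filter_sum_abundance(exp, min_total=10)
exp = ax.filter_prevalence(exp, min_fraction=0.1)
print("after TSS + low-abundance/prevalence filters:", exp)

exp = ax.sort_by_metadata(exp, "samples", ["group", "plate"])
exp = ax.cluster_order(exp, axis="features")

out = ax.export_html(exp, ax.HeatmapSpec(sample_bar_fields=["group", "plate"]),
                     "heatmap_demo.html")
print("heatmap written to", out)
print("operations recorded:", [r["op_name"] for r in exp.history])
# Every step above returned a new experiment and appended to the history,
# so ax.replay_history(original, exp.history) rebuilds this exact view.
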