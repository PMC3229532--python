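"""Regression of expression divergence on Ks and WGD-event codes.

For the WGD pairs (events alpha/beta/gamma coded 1/2/3) the three linear
models d ~ Ks, d ~ W and d ~ Ks + W are compared on adjusted R^2 and AIC;
a smoothing spline with 10 effective degrees of freedom traces the d-Ks
trend, and correlation tests with Fisher-z power analysis round out the
picture."""

import numpy as np
import pandas as pd

from common import CONFIG, RESULTS, load_corpus
from dupmodes.dup_classifier import DuplicationMode
from dupmodes.expression import pair_expression_stats
from dupmodes.seq_divergence import CodonAlignment, nei_gojobori
from dupmodes.stats_models import (
    WGD_CODES_ARABIDOPSIS,
    correlation_power,
    correlation_test,
    encode_wgd_events,
    regress_d,
    spline_trend,
)
from dupmodes.synthetic_data import simulate_expression, simulate_sequences


def main() -> None:
    annotation, anchors, hits, truth = load_corpus()
    matrix = simulate_expression(CONFIG, truth.pairs, annotation.gene_ids)
    seqs = simulate_sequences(CONFIG, truth.pairs)

    wgd_pairs = truth.pairs_of_mode(DuplicationMode.WGD)
    stats_df = pair_expression_stats(
        matrix, [(p.gene_a, p.gene_b, p.mode.value) for p in wgd_pairs]
    )
    ks, events = [], []
    for p in wgd_pairs:
        res = nei_gojobori(CodonAlignment(seqs.cds[p.gene_a], seqs.cds[p.gene_b]))
        ks.append(res.ks if res.ks_valid else np.nan)
        events.append(p.event)
    stats_df["ks"] = ks
    stats_df["w"] = encode_wgd_events(events, WGD_CODES_ARABIDOPSIS)

    print("model comparison on WGD pairs:")
    for model in ("ks", "w", "ks+w"):
        res = regress_d(stats_df, model=model)
        coef = ", ".join(f"{k}={v:.3f}" for k, v in res.params.items())
        print(f"  d ~ {model:5s}  adjR2 = {res.adj_r2:7.4f}  AIC = {res.aic:9.2f}  ({coef})")

    valid = stats_df.dropna(subset=["ks"])
    r, p = correlation_test(valid["d"], valid["ks"])
    power = correlation_power(r if abs(r) < 1 else 0.99, len(valid))
    print(f"\nd vs Ks: r = {r:.3f}, p = {p:.3g}, Fisher-z power = {power:.3f}")

    fit = spline_trend(valid["ks"].to_numpy(), valid["d"].to_numpy(), df=10)
    grid = np.linspace(valid["ks"].min(), valid["ks"].max(), 25)
    trend = pd.DataFrame({"ks": grid, "d_fitted": fit(grid)})
    RESULTS.mkdir(exist_ok=True)
    trend.to_csv(RESULTS / "spline_trend.tsv", sep="\t", index=False)
    print(f"spline effective df: {fit.effective_df:.2f}; wrote {RESULTS/'spline_trend.tsv'}")

    # The corpus plants per-mode expression correlation independently of Ks,
    # so no d-Ks coupling exists there (and none is found above).  To show
    # the model-comparison machinery on data where both Ks and the WGD code
    # genuinely drive d, fit the three models on a controlled simulation.
    rng = np.random.default_rng(CONFIG.seed)
    n = 5_000
    ks_sim = rng.uniform(0.0, 3.0, n)
    w_sim = rng.integers(1, 4, n).astype(float)
    d_sim = 0.56 + 0.05 * ks_sim + 0.05 * w_sim + 0.2 * rng.standard_normal(n)
    sim_df = pd.DataFrame({"d": d_sim, "ks": ks_sim, "w": w_sim})
    print("\nmodel comparison on planted d = 0.56 + 0.05 Ks + 0.05 W + noise:")
    best = None
    for model in ("ks", "w", "ks+w"):
        res = regress_d(sim_df, model=model)
        coef = ", ".join(f"{k}={v:.3f}" for k, v in res.params.items())
        print(f"  d ~ {model:5s}  adjR2 = {res.adj_r2:7.4f}  AIC = {res.aic:9.2f}  ({coef})")
        if best is None or res.aic < best[1]:
            best = (model, res.aic)
    print(f"lowest AIC: d ~ {best[0]} (the model with both predictors)")


if __name__ == "__main__":
    main()
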