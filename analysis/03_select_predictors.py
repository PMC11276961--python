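"""Jackknife variable importance and the |r| > 0.7 collinearity screen.

For each species: fit the quadratic-logistic preliminary model, measure the
cross-validated AUC drop from leaving each of the 30 candidate predictors
out, then resolve collinear pairs in favour of the more important member.

Writes results/importance.csv and results/retained_predictors.csv.
"""

from pathlib import Path

import pandas as pd

import rangeshift as rs
from rangeshift.pipeline import ALL_PREDICTORS
from rangeshift.sdm import sample_pseudo_absences

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    world = rs.generate_world(rs.WorldConfig(seed=SEED))
    stack = world.predictor_stack()
    tbl = stack.table()
    candidates = [n for n in ALL_PREDICTORS if tbl[n].std(ddof=0) > 0]
    corr = rs.pearson_matrix(stack, names=candidates)

    rows, retained_rows = [], []
    for i, niche in enumerate(rs.demo_niches()):
        truth = rs.true_suitability(world, niche)
        occ = rs.thin_spatial(rs.filter_uncertainty(
            rs.sample_occurrences(truth, 600, seed=SEED + 10 * i)),
            5.0, seed=SEED + 10 * i + 1)
        prelim = sample_pseudo_absences(stack.subset(candidates), occ, 0,
                                        seed=SEED + 10 * i + 2)
        imp = rs.jackknife_importance(stack, prelim.presence, prelim.absence,
                                      seed=SEED + 10 * i + 2)
        kept = rs.select_predictors(corr, imp, 0.7)
        retained_rows.append({"species": niche.species,
                              "n_retained": len(kept),
                              "retained": " ".join(kept)})
        for name in candidates:
            rows.append({"species": niche.species, "predictor": name,
                         "importance": imp[name], "retained": name in kept})

    RESULTS.mkdir(exist_ok=True)
    imp_df = pd.DataFrame(rows)
    imp_df.to_csv(RESULTS / "importance.csv", index=False,
                  float_format="%.6f")
    ret_df = pd.DataFrame(retained_rows)
    ret_df.to_csv(RESULTS / "retained_predictors.csv", index=False)

    for sp, grp in imp_df.groupby("species"):
        top = grp.nlargest(5, "importance")
        print(f"{sp}: top-5 predictors "
              f"{list(zip(top.predictor, top.importance.round(3)))}")
    print(ret_df.to_string(index=False))
    print("\nfor the band-niche species the true driver BIO1 tops the "
          "ranking; for the monotone warm-limited species the leave-one-out "
          "drop is diluted because collinear temperature proxies "
          "(BIO5/BIO6/BIO10/BIO11) substitute for BIO1 — redundancy, not "
          "absence of signal. The screen then keeps one member per "
          "correlated cluster, favouring the higher importance.")


if __name__ == "__main__":
    main()
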