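"""Cross-combine feature selectors with classifiers and rank the pipelines.

Builds the kidney's standardized train / internal / external matrices from
a simulated study, runs the 4 x 5 grid (LASSO, RFE, SBS, SFS crossed with
LR, SVM, RF, GBDT, MLPC), and scores every pipeline with the rank-sum
principle: within each of the 8 metric columns (accuracy, precision,
recall, AUC for internal and external validation) the best of the 20
models scores 20 and the worst 1, ties sharing the average position; the
model with the highest total over the 8 columns wins.
"""

from pmifusion import rank_models, run_cross_combination, select_best
from pmifusion.modelsearch import OrganData
from pmifusion.validation import default_study_matrices

data = default_study_matrices(seed=42)["kidney"]
organ = OrganData("kidney", data["train"], data["internal"], data["external"])

records = run_cross_combination(organ, seed=0)
ok = [r for r in records if not r.failed]
print(f"evaluated {len(ok)} (selector, classifier) pipelines for the kidney")

table = rank_models(ok)
print("\nrank-sum totals (top 5 of 20, max possible 160):")
print(table.totals.sort_values(ascending=False).head(5).to_string())

best = select_best(table)
rec = next(r for r in ok if r.spec.name == best)
print(
    f"\nbest kidney pipeline: {best} "
    f"(internal accuracy {rec.internal['accuracy']:.3f}, "
    f"external accuracy {rec.external['accuracy']:.3f})"
)
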