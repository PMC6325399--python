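"""Species x diet split-plot ANOVA of the fermentation responses.

For each simulated response (pH, NH3-N, total VFA, VFA molar
proportions, A:P ratio): cell means with pooled SEM, the split-plot
F-tests (species against animal-within-species; diet and interaction
against the residual), and Tukey comparisons of the six cells when the
interaction is significant.
"""

import sys
from pathlib import Path

import pandas as pd

from rumenprof import io as rio
from rumenprof import SimConfig, simulate_study, split_plot_anova, summarize_means, tukey_pairwise
from rumenprof.splitplot import significance_label

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260927
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = simulate_study(SimConfig(), seed=SEED)
    records = study.fermentation
    rows = []
    for response in records["response"].unique():
        result = split_plot_anova(records, response)
        means = summarize_means(records, response)
        rio.write_table(
            result.table.reset_index(names="effect"),
            OUT / f"anova_{response.replace(':', '_')}.tsv",
        )
        row = {"response": response, "sem": means.sem}
        for effect, key in (("species", "species"), ("diet", "diet"), ("species:diet", "interaction")):
            p = result.p(effect)
            row[f"p_{key}"] = p
            row[f"{key}_call"] = significance_label(p)
        rows.append(row)
        if result.p("species:diet") < 0.05:
            resid = result.table.loc["residual"]
            tukey = tukey_pairwise(
                means.means, float(resid["ms"]), int(resid["df"]), means.n_per_cell
            )
            rio.write_table(tukey, OUT / f"tukey_{response.replace(':', '_')}.tsv")

    summary = pd.DataFrame(rows)
    rio.write_table(summary, OUT / "anova_summary.tsv")
    print(summary.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
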