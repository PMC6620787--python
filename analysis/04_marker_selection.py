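"""LOOCV stability selection of marker OTUs on the 54 immature samples.

CSS-normalizes the screened immature table, then runs one shadow-feature
selection + random forest classifier per leave-one-out fold (54 folds),
and keeps as markers the OTUs selected in more than 90% of folds
(>= 50 of 54).  Writes the marker report and the Fig-2-style
rank-frequency table.
"""

import json
from pathlib import Path

from daquscope.markers import SelectionParams, loocv_markers, rank_frequency_table
from daquscope.otu_core import filter_low_occupancy, read_otu_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20190704


def main() -> None:
    table = read_otu_table(OUT / "otu_table.tsv", OUT / "metadata.tsv")
    imm = filter_low_occupancy(table.select_samples(table.samples_in_group("W", "Y")))
    print(f"immature cohort: {imm.n_samples} samples, {imm.n_otus} screened OTUs")

    params = SelectionParams(n_trees=100, max_iterations=40, seed=SEED)
    report = loocv_markers(imm, params)
    print(f"LOOCV: {report.n_folds} folds / classifiers; "
          f"prediction accuracy {report.accuracy:.2f}")
    print(f"marker cutoff: selected in >= {report.cutoff} of {report.n_folds} folds")
    print(f"markers ({len(report.markers)}): {report.markers}")

    truth = json.loads((OUT / "community_truth.json").read_text())
    spiked = {m[0] for m in truth["marker_otus"]}
    print(f"spiked OTUs recovered: {len(spiked & set(report.markers))} of {len(spiked)}")

    rf = rank_frequency_table(report, min_folds=10)
    rf.to_csv(OUT / "marker_rank_frequency.tsv", sep="\t")
    with open(OUT / "marker_report.json", "w") as fh:
        json.dump(
            {
                "n_folds": report.n_folds,
                "accuracy": report.accuracy,
                "cutoff": report.cutoff,
                "markers": report.markers,
                "selected_fold_count": report.selected_fold_count,
                "predictions": report.predictions,
            },
            fh,
            indent=1,
        )


if __name__ == "__main__":
    main()
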