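#!/usr/bin/env python
"""Profile the six population strata for the 2020 study year.

Totals, the pooled rate, the unweighted cross-city mean and SD of annual
IMR, and the consistency label each stratum earns from that SD.
"""

from _common import DATA_CSV, RESULTS, STUDY_YEAR
from epichannel import summarize_groups
from epichannel.io import read_dataset, write_summary

OUT_CSV = RESULTS / "group_summary_2020.csv"


def main() -> None:
    if not DATA_CSV.exists():
        raise SystemExit(f"{DATA_CSV} not found - run 01_simulate.py first")
    records = read_dataset(DATA_CSV)
    summary = summarize_groups(records, STUDY_YEAR)
    write_summary(summary, OUT_CSV)
    print(f"wrote group summary to {OUT_CSV}\n")
    cols = ["group_name", "n_cities", "total_births", "total_deaths",
            "pooled_imr", "imr_mean", "imr_sd", "classification"]
    print(summary[cols].round(1).to_string(index=False))
    print(
        "\nEvery stratum has the same underlying mortality (~11.6 per 1,000 "
        "births), yet the cross-city SD grows several-fold as cities shrink; "
        "the label tracks that dispersion, not the level."
    )


if __name__ == "__main__":
    main()
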