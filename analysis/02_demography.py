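#!/usr/bin/env python
"""Demographic analysis of the synthetic studbook.

Computes pedigree size, completeness, equivalent complete generations,
the target population, the realized effective population size from
per-individual rates of inbreeding, founder statistics, and the
purging-detectability threshold t_m implied by the estimated Ne.
Writes results/demography.json.
"""

import json
import pathlib

from purgekit.demography import cohort_bins, demography_report
from purgekit.pedigree import load_pedigree
from purgekit.purging import t_m

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ped = load_pedigree(BASE / "synthetic_studbook" / "pedigree.csv")
    report = demography_report(ped)
    payload = report.to_dict()
    payload["tm_no_selfing"] = round(t_m(report.Ne, "no_selfing"), 2)
    payload["tm_exact"] = round(t_m(report.Ne, "exact"), 2)
    payload["cohort_bins"] = cohort_bins(ped)
    (BASE / "demography.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"N = {payload['N']}, %PC = {payload['pct_complete']:.1f}")
    print(f"mean EqG (TP) = {payload['mean_EqG']:.2f} +- {payload['SE_EqG']:.2f}")
    print(f"Ne = {payload['Ne']:.2f} +- {payload['SE_Ne']:.2f}  (N_TP = {payload['N_TP']})")
    print(f"founders: AN_f = {payload['AN_f']}, N_f = {payload['N_f']}, N_ef = {payload['N_ef']:.2f}")
    print(f"t_m = {payload['tm_no_selfing']} generations (no-selfing approximation)")
    print(f"wrote {BASE/'demography.json'}")


if __name__ == "__main__":
    main()
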