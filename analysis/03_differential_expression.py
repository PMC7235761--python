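#!/usr/bin/env python
"""Differential-expression screens between patient groups (Wilcoxon + BH)
and clinical-parameter associations within the prostatectomy (LPC) arm:
PSA / T-stage / grade-group strata, CAPRA-S correlation, and BCR-free
survival by univariate Cox regression."""

import warnings
from pathlib import Path

import bcap
from bcap import Group
from bcap.diffexpr import comparison_table
from bcap.qpcr import read_sample_table
from bcap.qpcr import read_normalized_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    norm = read_normalized_table(ROOT / "normalized_dcq.tsv")
    samples = read_sample_table(ROOT / "cohort" / "samples.tsv")

    for ga, gb, name in [
        (Group.BPH, Group.APC, "BPH_vs_APC"),
        (Group.LPC, Group.APC, "LPC_vs_APC"),
        (Group.TRUSBX_BENIGN, Group.TRUSBX_MALIGNANT, "TRUSbx_benign_vs_malignant"),
    ]:
        res = bcap.compare_groups(norm, samples, ga, gb, alpha=0.05)
        tab = comparison_table(res).sort_values("p_adjusted")
        tab.to_csv(ROOT / f"diffexpr_{name}.tsv", sep="\t", index=False)
        up = int((tab["significant"] & (tab["direction"] == "up")).sum())
        dn = int((tab["significant"] & (tab["direction"] == "down")).sum())
        print(f"{name}: {up} up / {dn} down at BH 0.05")
        top = tab.head(3)[["mirna_id", "fold_change_signed", "p_adjusted"]]
        print(top.to_string(index=False), "\n")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        assoc = bcap.clinical_associations(norm, samples, alpha=0.05)
    import pandas as pd

    at = pd.DataFrame([vars(a) for a in assoc])
    at.to_csv(ROOT / "clinical_associations.tsv", sep="\t", index=False)
    for ep, grp in at.groupby("endpoint"):
        nsig = int((grp["p_adjusted"] < 0.05).sum())
        print(f"endpoint {ep}: {nsig} significant of {len(grp)} tested")


if __name__ == "__main__":
    main()
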