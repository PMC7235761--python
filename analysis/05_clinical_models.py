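#!/usr/bin/env python
"""Clinical combination models: logistic regression of biopsy outcome on the
chosen ratio score with PSA (and DRE + age), trained on the training split
only, plus the CAPRA-S risk-group distribution of the prostatectomy arm."""

import json
import warnings
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

import bcap
from bcap import Group
from bcap.clinical import SeparationWarning
from bcap.qpcr import Dre, read_normalized_table, read_sample_table

SEED = 42
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    norm = read_normalized_table(ROOT / "normalized_dcq.tsv")
    samples = read_sample_table(ROOT / "cohort" / "samples.tsv")
    by_id = {r.sample_id: r for r in samples}
    chosen = json.loads((ROOT / "chosen_model.json").read_text())
    model = bcap.RatioModel(tuple(chosen["numerator"]), tuple(chosen["denominator"]))
    scores = bcap.score_ratio_model(model, norm)

    split = bcap.split_train_test([r.sample_id for r in samples], 0.66, SEED)
    trus = {Group.TRUSBX_BENIGN: 0, Group.TRUSBX_MALIGNANT: 1}
    sets = {
        "train": [s for s in split.train_ids if by_id[s].group in trus],
        "test": [s for s in split.test_ids if by_id[s].group in trus],
    }

    def features(ids, names):
        rows, kept = [], []
        for s in ids:
            r = by_id[s]
            vals = {"bCaP": scores.get(s, np.nan),
                    "PSA": np.nan if r.psa is None else r.psa,
                    "DRE": {Dre.POSITIVE: 1.0, Dre.NEGATIVE: 0.0}.get(r.dre, np.nan),
                    "age": np.nan if r.age is None else r.age}
            row = [vals[n] for n in names]
            if np.isfinite(row).all():
                rows.append(row)
                kept.append(s)
        return np.array(rows), kept

    out = {}
    for names in (["bCaP", "PSA"], ["bCaP", "PSA", "DRE", "age"]):
        key = "+".join(names)
        Xtr, ktr = features(sets["train"], names)
        ytr = np.array([trus[by_id[s].group] for s in ktr])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            spec, _ = bcap.fit_logistic(Xtr, ytr, names, seed=SEED)
        Xte, kte = features(sets["test"], names)
        yte = np.array([trus[by_id[s].group] for s in kte])
        auc_tr = bcap.roc_auc(bcap.predict_logistic(spec, Xtr), ytr).auc
        auc_te = bcap.roc_auc(bcap.predict_logistic(spec, Xte), yte).auc
        out[key] = {"auc_train": auc_tr, "auc_test": auc_te,
                    "n_train": len(ktr), "n_test": len(kte),
                    "separation": spec.separation}
        print(f"{key}: train AUC {auc_tr:.3f} (n={len(ktr)}), "
              f"test AUC {auc_te:.3f} (n={len(kte)})"
              + ("  [separated]" if spec.separation else ""))
    (ROOT / "logistic_models.json").write_text(json.dumps(out, indent=2))

    # CAPRA-S distribution in the prostatectomy arm
    risks = []
    for r in samples:
        if r.group == Group.LPC and r.pathology is not None:
            try:
                risks.append(bcap.capra_s(r.pathology).risk_group)
            except ValueError:
                pass
    print("CAPRA-S risk groups (LPC):", dict(Counter(risks)))

    # BCR-free survival vs the ratio score in LPC
    lpc = [r for r in samples if r.group == Group.LPC and r.survival is not None]
    ids = [r.sample_id for r in lpc]
    mask = np.isfinite(scores[ids].to_numpy())
    hr, ci, p = bcap.cox_univariate(
        np.array([r.survival.time_months for r in lpc])[mask],
        np.array([r.survival.bcr_event for r in lpc])[mask],
        scores[ids].to_numpy()[mask],
    )
    print(f"BCR Cox, score in LPC: HR {hr:.2f} (95% CI {ci[0]:.2f}-{ci[1]:.2f}), p {p:.2g}")


if __name__ == "__main__":
    main()
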