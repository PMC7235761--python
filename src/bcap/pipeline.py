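"""End-to-end orchestration: simulate -> validate -> normalize -> diffexpr ->
ratio-model search -> clinical combination, into one reproducible run
directory.  One global seed governs every stochastic stage; every output is
stamped with the seed, a config hash, and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import LogisticModelSpec, fit_logistic, predict_logistic
from .diffexpr import compare_groups, comparison_table
from .preprocess import (
    DEFAULT_REFERENCE_PAIR,
    NormalizationSpec,
    correct_batch,
    normalize_delta_cq,
    normfinder_stability,
)
from .qpcr import CqMatrix, Dre, Group, SampleRecord, read_cq_table, read_sample_table, validate_cohort, write_sample_table
from .ratio import (
    RatioModel,
    SearchConfig,
    evaluate_model,
    roc_auc,
    score_ratio_model,
    search_best_model,
    split_train_test,
)
from .simulate import SyntheticConfig, generate_cohort


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    simulate: bool = True
    cq_path: str | None = None
    samples_path: str | None = None
    fraction: float = 0.66
    top_k: int = 20
    detection_threshold: float = 0.90
    alpha: float = 0.05
    lod_cq: float = 37.0
    reference_pair: tuple[str, str] = DEFAULT_REFERENCE_PAIR
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if syn:
            cfg.synthetic = SyntheticConfig(**syn)
        if "reference_pair" in raw:
            cfg.reference_pair = tuple(raw["reference_pair"])
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, Group):
                return o.value
            return o

        payload = enc(self)
        payload.pop("outdir", None)  # where results land is not part of the analysis
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write tables + report under the run dir.

    Returns a dict of in-memory artifacts (matrices, chosen model, report).
    No stage mutates an upstream artifact; reruns with the same config are
    bit-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/load"
    try:
        if config.simulate:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            cq, samples, truth = generate_cohort(syn)
            cq.write(out / "cq_matrix.tsv")
            write_sample_table(samples, out / "samples.tsv")
        else:
            truth = None
            if not config.cq_path or not Path(config.cq_path).exists():
                raise FileNotFoundError(f"Cq matrix not found: {config.cq_path}")
            if not config.samples_path or not Path(config.samples_path).exists():
                raise FileNotFoundError(f"annotation not found: {config.samples_path}")
            cq = read_cq_table(config.cq_path, lod_cq=config.lod_cq)
            samples = read_sample_table(config.samples_path)

        stage = "validate"
        report_val = validate_cohort(cq, samples)

        stage = "normalize"
        batches = [r.batch for r in samples]
        corrected = correct_batch(cq, batches)
        groups = [r.group.value for r in samples]
        stability = normfinder_stability(corrected, groups)
        spec = NormalizationSpec(tuple(config.reference_pair))
        norm = normalize_delta_cq(corrected, spec)
        norm.write(out / "normalized_dcq.tsv")
        stability.pair_ranking.head(50).to_csv(out / "normfinder_pairs.tsv", sep="\t", index=False)

        stage = "diffexpr"
        de_tables = {}
        for ga, gb, name in [
            (Group.BPH, Group.APC, "BPH_vs_APC"),
            (Group.LPC, Group.APC, "LPC_vs_APC"),
            (Group.TRUSBX_BENIGN, Group.TRUSBX_MALIGNANT, "TRUSbx_benign_vs_malignant"),
        ]:
            res = compare_groups(norm, samples, ga, gb, alpha=config.alpha)
            tab = comparison_table(res)
            tab.to_csv(out / f"diffexpr_{name}.tsv", sep="\t", index=False)
            de_tables[name] = tab

        stage = "search"
        split = split_train_test([r.sample_id for r in samples], config.fraction, config.seed)
        by_id = {r.sample_id: r for r in samples}
        trus = {Group.TRUSBX_BENIGN: 0, Group.TRUSBX_MALIGNANT: 1}
        train_trus = [s for s in split.train_ids if by_id[s].group in trus]
        test_trus = [s for s in split.test_ids if by_id[s].group in trus]
        y_train = pd.Series({s: trus[by_id[s].group] for s in train_trus})
        y_test = pd.Series({s: trus[by_id[s].group] for s in test_trus})
        sc = SearchConfig(top_k=config.top_k, detection_threshold=config.detection_threshold)
        from .ratio import rank_candidates

        candidates = rank_candidates(norm, y_train, sc, cq=corrected)
        search = search_best_model(norm, y_train, candidates)
        scores = score_ratio_model(search.best_model, norm)
        psa = pd.Series({r.sample_id: np.nan if r.psa is None else r.psa for r in samples})
        labels_all = pd.concat([y_train, y_test])
        subsets = {
            "train_TRUSbx": (train_trus, labels_all),
            "test_TRUSbx": (test_trus, labels_all),
        }
        for g in (Group.BPH, Group.LPC, Group.APC):
            ids_tr = [s for s in split.train_ids if by_id[s].group == g]
            ids_te = [s for s in split.test_ids if by_id[s].group == g]
            subsets[f"train_{g.value}"] = (ids_tr, None)
            subsets[f"test_{g.value}"] = (ids_te, None)
        evaluation = evaluate_model(search.best_model, norm, subsets, psa=psa)
        search.ranking.to_csv(out / "model_ranking.tsv", sep="\t", index=False)

        stage = "combine"
        logistic: dict[str, dict] = {}

        def features_for(ids, names):
            rows, kept = [], []
            for s in ids:
                r = by_id[s]
                row = []
                ok = np.isfinite(scores.get(s, np.nan))
                for nm in names:
                    if nm == "bCaP":
                        row.append(scores.get(s, np.nan))
                    elif nm == "PSA":
                        row.append(np.nan if r.psa is None else r.psa)
                        ok = ok and r.psa is not None
                    elif nm == "DRE":
                        row.append({Dre.POSITIVE: 1.0, Dre.NEGATIVE: 0.0}.get(r.dre, np.nan))
                        ok = ok and r.dre != Dre.UNKNOWN
                    elif nm == "age":
                        row.append(np.nan if r.age is None else r.age)
                        ok = ok and r.age is not None
                if ok and np.isfinite(row).all():
                    rows.append(row)
                    kept.append(s)
            return np.array(rows, dtype=float), kept

        for names in (["bCaP", "PSA"], ["bCaP", "PSA", "DRE", "age"]):
            key = "+".join(names)
            Xtr, kept_tr = features_for(train_trus, names)
            ytr = y_train[kept_tr].to_numpy()
            model, _ = fit_logistic(Xtr, ytr, names, seed=config.seed)
            Xte, kept_te = features_for(test_trus, names)
            entry = {
                "model": dataclasses.asdict(model) | {"loglik_path": None},
                "auc_train": roc_auc(predict_logistic(model, Xtr), ytr).auc,
            }
            if len(kept_te) and y_test[kept_te].nunique() == 2:
                entry["auc_test"] = roc_auc(
                    predict_logistic(model, Xte), y_test[kept_te].to_numpy()
                ).auc
            logistic[key] = entry
            model.to_json(out / f"logistic_{key.replace('+', '_')}.json")

        stage = "report"
        report = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
            "validation": {
                "ok": report_val.ok,
                "group_counts": report_val.group_counts,
                "n_undetected_mirnas": len(report_val.undetected_mirnas),
            },
            "normfinder_best_pair": list(stability.best_pair),
            "reference_pair_used": list(config.reference_pair),
            "split": {"n_train": len(split.train_ids), "n_test": len(split.test_ids)},
            "diffexpr": {
                name: {
                    "n_significant": int(tab["significant"].sum()),
                    "n_up": int((tab["significant"] & (tab["direction"] == "up")).sum()),
                    "n_down": int((tab["significant"] & (tab["direction"] == "down")).sum()),
                }
                for name, tab in de_tables.items()
            },
            "best_model": {
                "model": str(search.best_model),
                "numerator": list(search.best_model.numerator),
                "denominator": list(search.best_model.denominator),
                "training_oriented_auc": search.best_auc,
                "orientation": search.orientation,
            },
            "evaluation": evaluation,
            "logistic": {
                k: {kk: vv for kk, vv in v.items() if kk != "model"} for k, v in logistic.items()
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "cq": cq,
        "samples": samples,
        "truth": truth,
        "normalized": norm,
        "stability": stability,
        "diffexpr": de_tables,
        "split": split,
        "search": search,
        "evaluation": evaluation,
        "logistic": logistic,
        "report": report,
    }
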