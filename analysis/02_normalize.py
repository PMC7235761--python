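#!/usr/bin/env python
"""Preprocess the cohort: remove additive batch offsets, rank candidate
reference miRNAs by NormFinder stability, and normalize to the reference
pair (dCq = mean reference Cq - target Cq).  Writes the normalized matrix
and the stability ranking."""

from pathlib import Path

import bcap
from bcap.qpcr import read_cq_table, read_sample_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cq = read_cq_table(ROOT / "cohort" / "cq_matrix.tsv")
    samples = read_sample_table(ROOT / "cohort" / "samples.tsv")
    report = bcap.validate_cohort(cq, samples)
    assert report.ok, "cohort annotation mismatch"

    corrected = bcap.correct_batch(cq, [r.batch for r in samples])
    stability = bcap.normfinder_stability(corrected, [r.group.value for r in samples])
    print(f"NormFinder candidates (detected in all samples): {len(stability.stability)}")
    print(f"most stable single miRNAs:\n{stability.stability.nsmallest(5)}")
    print(f"most stable pair: {stability.best_pair}")

    spec = bcap.NormalizationSpec()
    norm = bcap.normalize_delta_cq(corrected, spec)
    norm.write(ROOT / "normalized_dcq.tsv")
    stability.pair_ranking.head(100).to_csv(ROOT / "normfinder_pairs.tsv", sep="\t", index=False)
    print(f"normalized to {spec.reference_pair}; wrote {ROOT / 'normalized_dcq.tsv'}")


if __name__ == "__main__":
    main()
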