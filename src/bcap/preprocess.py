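"""Batch correction, reference-miRNA stability selection, and dCq normalization.

The normalization chain is: (1) remove additive per-(miRNA, batch) offsets;
(2) pick the most stably expressed miRNA pair by the NormFinder model-based
stability value; (3) normalize every miRNA to the mean Cq of the reference
pair, dCq = mean(Cq_ref1, Cq_ref2) - Cq_target, so higher dCq = more abundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .qpcr import CqMatrix, NormalizedMatrix

DEFAULT_REFERENCE_PAIR = ("hsa-miR-23a-3p", "hsa-miR-93-5p")


@dataclass
class NormalizationSpec:
    """Reference pair used for dCq normalization.

    The default pair is the panel's empirically most stable pair of plasma
    miRNAs (miR-23a-3p and miR-93-5p).
    """

    reference_pair: tuple[str, str] = DEFAULT_REFERENCE_PAIR

    def __post_init__(self) -> None:
        a, b = self.reference_pair
        if a == b:
            raise ValueError("reference pair must be two distinct miRNAs")


@dataclass
class StabilityResult:
    """NormFinder output: per-miRNA stability (lower = more stable) and the
    ranked candidate pairs."""

    stability: pd.Series  # index: miRNA id
    pair_ranking: pd.DataFrame = field(repr=False)  # columns: mirna_a, mirna_b, stability
    best_pair: tuple[str, str] = ("", "")


def correct_batch(cq: CqMatrix, batch: list[str] | pd.Series) -> CqMatrix:
    """Remove additive per-(miRNA, batch) offsets from detected Cq values.

    For each miRNA the batch mean of detected cells minus the grand mean of
    detected cells is subtracted within each batch (a one-way fixed-effect
    fit per miRNA).  Missing cells stay missing; each miRNA's grand mean is
    preserved.  A single batch is the identity.
    """
    batch = list(batch)
    if len(batch) != len(cq.sample_ids):
        raise ValueError(
            f"batch vector length {len(batch)} != number of samples {len(cq.sample_ids)}"
        )
    v = cq.values
    grand = v.mean(axis=1)
    out = v.copy()
    codes = pd.Series(batch, index=v.columns)
    for b in codes.unique():
        cols = codes.index[codes == b]
        offset = v[cols].mean(axis=1) - grand  # NaN-aware means
        out[cols] = v[cols].sub(offset.fillna(0.0), axis=0)
    return CqMatrix(out)


def _normfinder_core(
    X: np.ndarray, group_codes: np.ndarray, n_groups: int
) -> np.ndarray:
    """Stability values for rows of X (genes x samples), given group coding.

    Implements the model-based stability estimate: sample-wise centering over
    the candidate genes, per-(gene, group) mean deviations d_gi shrunk toward
    zero by an empirical-Bayes factor gamma^2 / (gamma^2 + s^2_gi / n_i), and
    stability(g) = mean over groups of |d~_gi| + sqrt(var(d~_gi)) where
    var(d~_gi) is the posterior variance of the shrunken deviation.
    """
    # (1) remove per-sample loading: center each sample over candidate genes
    Xc = X - X.mean(axis=0, keepdims=True)
    n_genes = Xc.shape[0]
    d = np.empty((n_genes, n_groups))
    s2_over_n = np.empty((n_genes, n_groups))
    grand = Xc.mean(axis=1, keepdims=True)
    for i in range(n_groups):
        cols = group_codes == i
        n_i = cols.sum()
        gm = Xc[:, cols].mean(axis=1)
        d[:, i] = gm - grand[:, 0]
        s2 = Xc[:, cols].var(axis=1, ddof=1)
        s2_over_n[:, i] = s2 / n_i
    gamma2 = d.var(axis=0, ddof=1)  # across-gene variance of deviations, per group
    gamma2 = np.maximum(gamma2, 1e-12)
    shrink = gamma2[None, :] / (gamma2[None, :] + s2_over_n)
    d_shrunk = d * shrink
    post_var = s2_over_n * shrink
    return (np.abs(d_shrunk) + np.sqrt(post_var)).mean(axis=1)


def normfinder_stability(
    cq: CqMatrix,
    groups: list[str] | pd.Series,
    min_group_size: int = 3,
) -> StabilityResult:
    """Rank candidate reference miRNAs by NormFinder stability (lower = better).

    Candidates are restricted to miRNAs detected in every sample considered.
    Pair stability is the same statistic recomputed on the per-sample mean of
    the two candidates (sharing the single-gene centering and shrinkage
    variance).  Ties break lexicographically on miRNA id.
    """
    groups = pd.Series(list(groups), index=cq.sample_ids)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("NormFinder needs at least two groups")
    sizes = groups.value_counts()
    if (sizes < min_group_size).any():
        small = sizes[sizes < min_group_size].index.tolist()
        raise ValueError(f"groups below minimum size {min_group_size}: {small}")

    full = cq.values.notna().all(axis=1)
    candidates = cq.values.index[full]
    if len(candidates) == 0:
        raise ValueError("no candidate miRNA detected in all samples")
    X = cq.values.loc[candidates].to_numpy(dtype=float)
    codes = np.asarray(groups.map({g: i for i, g in enumerate(levels)}), dtype=int)

    stab = _normfinder_core(X, codes, len(levels))
    stability = pd.Series(stab, index=candidates).sort_index()

    # Pair stability: pseudo-genes = per-sample mean of each candidate pair,
    # evaluated jointly after the same per-sample centering.
    pairs = list(combinations(sorted(candidates), 2))
    ia = {m: i for i, m in enumerate(candidates)}
    Xc = X - X.mean(axis=0, keepdims=True)
    idx_a = np.array([ia[a] for a, _ in pairs])
    idx_b = np.array([ia[b] for _, b in pairs])
    P = 0.5 * (Xc[idx_a] + Xc[idx_b])
    n_groups = len(levels)
    d = np.empty((len(pairs), n_groups))
    s2_over_n = np.empty((len(pairs), n_groups))
    grand = P.mean(axis=1, keepdims=True)
    # gamma^2 from the single-gene deviations (the across-gene spread)
    d_single = np.empty((X.shape[0], n_groups))
    for i in range(n_groups):
        cols = codes == i
        d_single[:, i] = Xc[:, cols].mean(axis=1) - Xc.mean(axis=1)
        gm = P[:, cols].mean(axis=1)
        d[:, i] = gm - grand[:, 0]
        s2_over_n[:, i] = P[:, cols].var(axis=1, ddof=1) / cols.sum()
    gamma2 = np.maximum(d_single.var(axis=0, ddof=1), 1e-12)
    shrink = gamma2[None, :] / (gamma2[None, :] + s2_over_n)
    pair_stab = (np.abs(d * shrink) + np.sqrt(s2_over_n * shrink)).mean(axis=1)

    ranking = pd.DataFrame(
        {
            "mirna_a": [a for a, _ in pairs],
            "mirna_b": [b for _, b in pairs],
            "stability": pair_stab,
        }
    ).sort_values(["stability", "mirna_a", "mirna_b"], kind="stable")
    ranking = ranking.reset_index(drop=True)
    best = (ranking.at[0, "mirna_a"], ranking.at[0, "mirna_b"])
    return StabilityResult(stability=stability, pair_ranking=ranking, best_pair=best)


def normalize_delta_cq(cq: CqMatrix, spec: NormalizationSpec) -> NormalizedMatrix:
    """dCq(g, j) = mean(Cq_ref1(j), Cq_ref2(j)) - Cq_g(j).

    A sample missing either reference yields an all-missing dCq column
    (no single-reference fallback, to avoid silent normalization drift).
    """
    a, b = spec.reference_pair
    for ref in (a, b):
        if ref not in cq.values.index:
            raise ValueError(f"reference miRNA {ref!r} absent from panel")
    ref_mean = (cq.values.loc[a] + cq.values.loc[b]) / 2.0  # NaN if either missing
    delta = cq.values.rsub(ref_mean, axis=1)
    return NormalizedMatrix(delta, reference_pair=(a, b))
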