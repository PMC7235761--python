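"""Group-wise differential expression and clinical association screens.

Per-miRNA comparisons use the Wilcoxon rank-sum (Mann-Whitney U) test on dCq
values with Benjamini-Hochberg adjustment within each comparison family.
ddCq = mean dCq(group_b) - mean dCq(group_a) is a log2 fold change; it is
also reported as a signed linear fold (+2^ddCq up, -2^-ddCq down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qpcr import Finding, Group, NormalizedMatrix, SampleRecord
from .clinical import capra_s


@dataclass
class ComparisonResult:
    mirna_id: str
    n_a: int
    n_b: int
    delta_delta_cq: float
    fold_change_signed: float
    p_raw: float
    p_adjusted: float
    direction: str  # "up" | "down" (group_b relative to group_a)
    significant: bool


@dataclass
class AssociationResult:
    mirna_id: str
    endpoint: str
    effect: float  # ddCq, Spearman rho, or hazard ratio
    p_raw: float
    p_adjusted: float


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic of x, p).

    Exact p by enumeration when both samples have at most 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_from_ddcq(ddcq: float) -> float:
    """Signed linear fold from a log2 fold change: +2^d if d >= 0 else -2^-d."""
    if not np.isfinite(ddcq):
        raise ValueError("ddCq must be finite")
    return float(2.0**ddcq) if ddcq >= 0 else float(-(2.0 ** (-ddcq)))


def percent_overlap(n_shared: int, n_total: int) -> float:
    """Percentage of one significant set also present in another, to one decimal."""
    return round(100.0 * n_shared / n_total, 1)


def compare_groups(
    norm: NormalizedMatrix,
    samples: list[SampleRecord],
    group_a: Group | str,
    group_b: Group | str,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Per-miRNA Wilcoxon screen of group_b versus group_a.

    ddCq = mean dCq(group_b) - mean dCq(group_a) on pairwise-complete samples;
    BH adjustment across all tested miRNAs of this comparison.
    """
    group_a, group_b = Group(group_a), Group(group_b)
    ids_a = [r.sample_id for r in samples if r.group == group_a]
    ids_b = [r.sample_id for r in samples if r.group == group_b]
    for g, ids in ((group_a, ids_a), (group_b, ids_b)):
        if not ids:
            raise ValueError(f"group {g.value} has no samples")
    va = norm.values[ids_a]
    vb = norm.values[ids_b]

    rows = []
    for mirna in norm.mirna_ids:
        xa = va.loc[mirna].dropna().to_numpy()
        xb = vb.loc[mirna].dropna().to_numpy()
        if xa.size == 0 or xb.size == 0:
            continue
        ddcq = float(xb.mean() - xa.mean())
        _, p = wilcoxon_rank_sum(xa, xb)
        rows.append((mirna, xa.size, xb.size, ddcq, p))
    if not rows:
        return []
    padj = bh_adjust([r[4] for r in rows])
    return [
        ComparisonResult(
            mirna_id=m,
            n_a=na,
            n_b=nb,
            delta_delta_cq=ddcq,
            fold_change_signed=fold_from_ddcq(ddcq),
            p_raw=p,
            p_adjusted=float(q),
            direction="up" if ddcq >= 0 else "down",
            significant=bool(q < alpha),
        )
        for (m, na, nb, ddcq, p), q in zip(rows, padj)
    ]


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def cox_univariate(time, event, covariate, max_iter: int = 100, tol: float = 1e-10):
    """Univariate Cox proportional-hazards fit by Newton-Raphson on the
    Breslow partial likelihood.  Returns (hazard ratio, (lo, hi), Wald p).

    Censoring at the last normal PSA is the caller's data contract.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if e.sum() < 2:
        raise ValueError("Cox fit requires at least two events")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    order = np.argsort(t)
    t, e, x = t[order], e[order], x[order]
    # per unique event time: number of deaths, sum of x over deaths, and the
    # start index of its risk set (t sorted ascending => suffix)
    uniq = np.unique(t[e])
    starts = np.searchsorted(t, uniq, side="left")
    d_counts = np.array([(e & (t == u)).sum() for u in uniq], dtype=float)
    dx_sums = np.array([x[e & (t == u)].sum() for u in uniq])

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w * x)[::-1])[::-1]
        s2 = np.cumsum((w * x * x)[::-1])[::-1]
        r0, r1, r2 = s0[starts], s1[starts], s2[starts]
        score = float(dx_sums.sum() - (d_counts * r1 / r0).sum())
        info = float((d_counts * (r2 / r0 - (r1 / r0) ** 2)).sum())
        if info <= 0:
            raise RuntimeError("singular information in Cox fit")
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    else:
        raise RuntimeError("Cox Newton-Raphson did not converge in 100 iterations")
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    return float(np.exp(beta)), ci, float(p)


def _dichotomous_screen(
    norm: NormalizedMatrix, ids_low: list[str], ids_high: list[str], endpoint: str
) -> list[AssociationResult]:
    rows = []
    for mirna in norm.mirna_ids:
        xl = norm.values.loc[mirna, ids_low].dropna().to_numpy()
        xh = norm.values.loc[mirna, ids_high].dropna().to_numpy()
        if xl.size == 0 or xh.size == 0:
            continue
        ddcq = float(xh.mean() - xl.mean())
        _, p = wilcoxon_rank_sum(xl, xh)
        rows.append((mirna, ddcq, p))
    padj = bh_adjust([r[2] for r in rows]) if rows else []
    return [
        AssociationResult(m, endpoint, eff, p, float(q))
        for (m, eff, p), q in zip(rows, padj)
    ]


def clinical_associations(
    norm: NormalizedMatrix, samples: list[SampleRecord], alpha: float = 0.05
) -> list[AssociationResult]:
    """Associations of miRNA levels with aggressiveness endpoints in LPC.

    Endpoints: PSA <=10 vs >10 ng/mL, pT <=T2 vs >=T3, grade group <=2 vs >2
    (Wilcoxon ddCq screens); Spearman correlation with the CAPRA-S score; and
    univariate Cox regression against BCR-free survival.  BH adjustment is
    applied within each endpoint family.  Endpoints with an empty side are
    skipped with a warning.
    """
    lpc = [r for r in samples if r.group == Group.LPC]
    if not lpc:
        raise ValueError("no LPC samples")
    out: list[AssociationResult] = []

    def try_screen(ids_low, ids_high, endpoint):
        if not ids_low or not ids_high:
            warnings.warn(f"endpoint {endpoint!r} skipped: one side empty", stacklevel=2)
            return
        out.extend(_dichotomous_screen(norm, ids_low, ids_high, endpoint))

    with_psa = [r for r in lpc if r.psa is not None]
    try_screen(
        [r.sample_id for r in with_psa if r.psa <= 10],
        [r.sample_id for r in with_psa if r.psa > 10],
        "PSA<=10_vs_>10",
    )
    with_t = [r for r in lpc if r.pathology is not None and r.pathology.t_stage is not None]
    try_screen(
        [r.sample_id for r in with_t if r.pathology.t_stage in ("T1", "T2")],
        [r.sample_id for r in with_t if r.pathology.t_stage in ("T3", "T4")],
        "pT<=T2_vs_>=T3",
    )
    with_g = [
        r for r in lpc if r.pathology is not None and r.pathology.gleason_grade_group is not None
    ]
    try_screen(
        [r.sample_id for r in with_g if r.pathology.gleason_grade_group <= 2],
        [r.sample_id for r in with_g if r.pathology.gleason_grade_group > 2],
        "GGG<=2_vs_>2",
    )

    # CAPRA-S Spearman correlation
    capra_ids, capra_vals = [], []
    for r in lpc:
        if r.pathology is None:
            continue
        try:
            capra_vals.append(capra_s(r.pathology).total)
            capra_ids.append(r.sample_id)
        except ValueError:
            continue
    if len(set(capra_vals)) < 2:
        warnings.warn("CAPRA-S endpoint skipped: score constant or unavailable", stacklevel=2)
    else:
        cs = pd.Series(capra_vals, index=capra_ids, dtype=float)
        rows = []
        for mirna in norm.mirna_ids:
            v = norm.values.loc[mirna, capra_ids]
            mask = v.notna()
            if mask.sum() < 3:
                continue
            rho, p = stats.spearmanr(v[mask], cs[mask])
            rows.append((mirna, float(rho), float(p)))
        padj = bh_adjust([r[2] for r in rows]) if rows else []
        out.extend(
            AssociationResult(m, "CAPRA-S_spearman", eff, p, float(q))
            for (m, eff, p), q in zip(rows, padj)
        )

    # univariate Cox vs BCR
    surv = [r for r in lpc if r.survival is not None]
    n_events = sum(r.survival.bcr_event for r in surv)
    if n_events < 2:
        warnings.warn("BCR Cox endpoint skipped: fewer than two events", stacklevel=2)
    else:
        sids = [r.sample_id for r in surv]
        tvec = np.array([r.survival.time_months for r in surv])
        evec = np.array([r.survival.bcr_event for r in surv])
        rows = []
        for mirna in norm.mirna_ids:
            v = norm.values.loc[mirna, sids].to_numpy()
            mask = np.isfinite(v)
            if evec[mask].sum() < 2 or np.ptp(v[mask]) == 0:
                continue
            try:
                hr, _, p = cox_univariate(tvec[mask], evec[mask], v[mask])
            except RuntimeError:
                continue
            rows.append((mirna, hr, p))
        padj = bh_adjust([r[2] for r in rows]) if rows else []
        out.extend(
            AssociationResult(m, "BCR_cox", eff, p, float(q))
            for (m, eff, p), q in zip(rows, padj)
        )
    return out
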