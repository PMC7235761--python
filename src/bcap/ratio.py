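"""ROC/AUC engine, train/test splitting, and exhaustive ratio-model search.

A ratio model partitions 2-4 miRNAs into a numerator and a denominator; on
the log2 (dCq) scale its score is the sum of numerator dCq minus the sum of
denominator dCq.  Balanced models (1/1 or 2/2) are invariant to per-sample
additive Cq shifts, so they need no normalization by construction.  The
search enumerates every model over a candidate panel, scores each sample,
and ranks models by oriented AUC for discriminating benign from malignant
biopsy outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .qpcr import CqMatrix, NormalizedMatrix


@dataclass(frozen=True)
class RatioModel:
    """A signed partition of 2-4 miRNAs: score = sum(num dCq) - sum(den dCq).

    Stored in canonical form (ids sorted within each side).
    """

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num = tuple(sorted(self.numerator))
        den = tuple(sorted(self.denominator))
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)
        if not (1 <= len(num) <= 2 and 1 <= len(den) <= 2):
            raise ValueError("each side of a ratio model holds 1 or 2 miRNAs")
        members = num + den
        if len(set(members)) != len(members):
            raise ValueError("numerator and denominator must be disjoint")
        if not 2 <= len(members) <= 4:
            raise ValueError("ratio models have 2-4 miRNAs")

    @property
    def size(self) -> int:
        return len(self.numerator) + len(self.denominator)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.numerator) | frozenset(self.denominator)

    @property
    def balanced(self) -> bool:
        return len(self.numerator) == len(self.denominator)

    def canonical_key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (self.numerator, self.denominator)

    def __str__(self) -> str:
        return f"{' * '.join(self.numerator)} / {' * '.join(self.denominator)}"


@dataclass
class SplitSpec:
    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    seed: int


@dataclass
class SearchConfig:
    top_k: int = 20
    detection_threshold: float = 0.90  # strict: keep if detected fraction > threshold

    def __post_init__(self) -> None:
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection_threshold must lie in (0, 1)")
        if self.top_k < 2:
            raise ValueError("top_k must be >= 2")


@dataclass
class RocResult:
    auc: float
    oriented_auc: float
    orientation: str  # "high-score-positive" | "low-score-positive"
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> RocResult:
    """AUC with the high-score => positive convention, plus its orientation.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    a = float(roc_auc_score(y, s))
    oriented = max(a, 1.0 - a)
    return RocResult(
        auc=a,
        oriented_auc=oriented,
        orientation="high-score-positive" if a >= 0.5 else "low-score-positive",
        n_pos=n_pos,
        n_neg=n_neg,
    )


def split_train_test(sample_ids: list[str], fraction: float = 0.66, seed: int = 0) -> SplitSpec:
    """Simple random split without stratification; |train| = round(fraction * n)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    ids = list(sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two samples to split")
    n_train = int(round(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return SplitSpec(train_ids=train, test_ids=test, fraction=fraction, seed=seed)


def detection_filter(cq: CqMatrix, sample_ids: list[str], threshold: float = 0.90) -> list[str]:
    """miRNAs detected in strictly more than ``threshold`` of the subset."""
    if not sample_ids:
        raise ValueError("sample subset is empty")
    rates = cq.detection_rates(list(sample_ids))
    return list(rates.index[rates > threshold])


def rank_candidates(
    norm: NormalizedMatrix,
    labels: pd.Series,
    config: SearchConfig,
    cq: CqMatrix | None = None,
) -> list[str]:
    """Top-k single-miRNA discriminators by oriented AUC, after detection filter.

    ``labels`` maps training-sample id -> 0 (benign) / 1 (malignant).  The
    detection filter is computed on the raw Cq matrix when given, else on the
    normalized matrix.  Ties break lexicographically; if fewer than top_k
    miRNAs survive, all are returned with a warning.
    """
    ids = list(labels.index)
    src = cq if cq is not None else None
    if src is not None:
        kept = detection_filter(src, ids, config.detection_threshold)
    else:
        rates = norm.values[ids].notna().mean(axis=1)
        kept = list(rates.index[rates > config.detection_threshold])
    y = labels.to_numpy().astype(int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("training subset must contain both outcomes")
    aucs = []
    for mirna in kept:
        v = norm.values.loc[mirna, ids].to_numpy(dtype=float)
        mask = np.isfinite(v)
        if (y[mask] == 1).sum() == 0 or (y[mask] == 0).sum() == 0:
            continue
        aucs.append((mirna, roc_auc(v[mask], y[mask]).oriented_auc))
    ranked = sorted(aucs, key=lambda t: (-t[1], t[0]))
    if len(ranked) < config.top_k:
        warnings.warn(
            f"only {len(ranked)} miRNAs survive the detection filter "
            f"(top_k = {config.top_k})",
            stacklevel=2,
        )
    return [m for m, _ in ranked[: config.top_k]]


def enumerate_ratio_models(panel: list[str], unordered: bool = False) -> list[RatioModel]:
    """All unique 2-, 3-, and 4-miRNA ratio models over a panel of m ids.

    Default counting convention (m = 20 gives 190 + 3,420 + 29,070 = 32,680):
    2-miRNA models are unordered pairs, C(m,2); 3-miRNA models are one per
    (trio, singleton) choice, C(m,3)*3; 4-miRNA models are ordered
    (numerator-pair, denominator-pair) selections, C(m,2)*C(m-2,2).  The
    convention deliberately counts size-4 reciprocals separately while
    folding size-2/3 reciprocals; ``unordered=True`` switches to fully
    unordered counting (size 4 becomes C(m,4)*3).  Canonical order, no
    duplicates.
    """
    ids = sorted(set(panel))
    if len(ids) != len(panel):
        raise ValueError("panel ids must be unique")
    m = len(ids)
    if m < 2:
        return []
    models: list[RatioModel] = []
    for a, b in combinations(ids, 2):
        models.append(RatioModel((a,), (b,)))
    for trio in combinations(ids, 3):
        for s in trio:
            pair = tuple(x for x in trio if x != s)
            models.append(RatioModel(pair, (s,)))
    if unordered:
        for quad in combinations(ids, 4):
            rest = quad[1:]
            for partner in rest:
                num = (quad[0], partner)
                den = tuple(x for x in rest if x != partner)
                models.append(RatioModel(num, den))
    else:
        for num in combinations(ids, 2):
            rest = [x for x in ids if x not in num]
            for den in combinations(rest, 2):
                models.append(RatioModel(num, den))
    return models


def score_ratio_model(model: RatioModel, matrix: NormalizedMatrix | CqMatrix) -> pd.Series:
    """Per-sample log2-scale score: sum over numerator minus sum over denominator.

    Works on dCq (NormalizedMatrix) or, for balanced models, equivalently on
    raw Cq with the sides swapped sign (lower Cq = more abundant), i.e.
    scoring a CqMatrix computes sum(den Cq) - sum(num Cq).  A sample missing
    any constituent gets a missing score.
    """
    v = matrix.values
    for mirna in (*model.numerator, *model.denominator):
        if mirna not in v.index:
            raise ValueError(f"model constituent {mirna!r} absent from matrix")
    num = v.loc[list(model.numerator)].sum(axis=0, skipna=False)
    den = v.loc[list(model.denominator)].sum(axis=0, skipna=False)
    if isinstance(matrix, CqMatrix):
        return den - num  # Cq scale is inverted relative to abundance
    return num - den


@dataclass
class SearchResult:
    best_model: RatioModel
    best_auc: float  # oriented training AUC
    orientation: str
    ranking: pd.DataFrame = field(repr=False)  # top models: model, oriented_auc
    candidates: list[str] = field(default_factory=list)


def _oriented_auc_rows(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise oriented AUC by average ranks (NaN-free input)."""
    R = rankdata(S, axis=1)
    n1 = int(y.sum())
    n0 = y.size - n1
    U = R[:, y == 1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    a = U / (n1 * n0)
    return np.maximum(a, 1.0 - a)


def search_best_model(
    norm: NormalizedMatrix,
    labels: pd.Series,
    candidates: list[str],
    keep_top: int = 50,
) -> SearchResult:
    """Exhaustively evaluate every ratio model over the candidate panel.

    Samples with a missing score are excluded per model.  Models are ranked
    by oriented training AUC; exact AUC ties (the pair-count AUC is discrete)
    are resolved by the standardized mean score difference between classes
    (Welch z), then by canonical form.
    """
    models = enumerate_ratio_models(candidates)
    if not models:
        raise ValueError("no models to evaluate")
    ids = list(labels.index)
    y = labels.to_numpy().astype(int)
    X = norm.values.loc[sorted(candidates), ids].to_numpy(dtype=float)
    order = {m: i for i, m in enumerate(sorted(candidates))}
    C = np.zeros((len(models), len(candidates)))
    for k, mod in enumerate(models):
        for m in mod.numerator:
            C[k, order[m]] = 1.0
        for m in mod.denominator:
            C[k, order[m]] = -1.0

    miss = ~np.isfinite(X)
    model_miss = (np.abs(C) @ miss.astype(float)) > 0  # sample missing any member
    S = C @ np.nan_to_num(X)
    aucs = np.full(len(models), np.nan)
    # group models by missing-sample pattern so each group is rank-vectorized
    patterns = np.packbits(model_miss, axis=1)
    _, inv = np.unique(patterns, axis=0, return_inverse=True)
    for g in np.unique(inv):
        rows = np.flatnonzero(inv == g)
        keep = ~model_miss[rows[0]]
        yk = y[keep]
        if (yk == 1).sum() == 0 or (yk == 0).sum() == 0:
            continue
        aucs[rows] = _oriented_auc_rows(S[np.ix_(rows, keep)], yk)
    if np.all(np.isnan(aucs)):
        raise ValueError("no model could be scored on both classes")

    amax = np.nanmax(aucs)
    tied = np.flatnonzero(aucs == amax)
    if tied.size > 1:
        zs = np.empty(tied.size)
        for i, k in enumerate(tied):
            keep = ~model_miss[k]
            sk, yk = S[k, keep], y[keep]
            m1, m0 = sk[yk == 1], sk[yk == 0]
            denom = np.sqrt(m1.var(ddof=1) / m1.size + m0.var(ddof=1) / m0.size)
            zs[i] = np.abs(m1.mean() - m0.mean()) / denom if denom > 0 else 0.0
        tied = tied[np.lexsort(([str(models[k].canonical_key()) for k in tied], -zs))]
    best_k = int(tied[0])
    best = models[best_k]
    # store the reported direction explicitly: higher score => positive class
    keep_best = ~model_miss[best_k]
    raw = roc_auc(S[best_k, keep_best], y[keep_best])
    orientation = raw.orientation
    if raw.auc < 0.5:
        best = RatioModel(best.denominator, best.numerator)
        orientation = "high-score-positive"  # after swapping the sides

    top_idx = np.argsort(-np.nan_to_num(aucs, nan=-1.0), kind="stable")[:keep_top]
    ranking = pd.DataFrame(
        {
            "model": [str(models[k]) for k in top_idx],
            "size": [models[k].size for k in top_idx],
            "oriented_auc": aucs[top_idx],
        }
    )
    return SearchResult(
        best_model=best,
        best_auc=float(amax),
        orientation=orientation,
        ranking=ranking,
        candidates=list(candidates),
    )


def evaluate_model(
    model: RatioModel,
    norm: NormalizedMatrix,
    subsets: dict[str, tuple[list[str], pd.Series | None]],
    psa: pd.Series | None = None,
) -> dict:
    """Score summaries and outcome AUCs per labeled subset, with PSA AUC beside.

    ``subsets`` maps a subset name to (sample ids, labels or None); labels, when
    given, are a 0/1 Series over (a superset of) those ids.  Subsets with one
    outcome class get score summaries but no AUC.
    """
    from .diffexpr import wilcoxon_rank_sum

    scores = score_ratio_model(model, norm)
    report: dict = {"model": str(model), "subsets": {}}
    for name, (ids, labels) in subsets.items():
        s = scores[ids].dropna()
        entry: dict = {
            "n": int(s.size),
            "score_mean": float(s.mean()) if s.size else float("nan"),
            "score_median": float(s.median()) if s.size else float("nan"),
            "score_q1": float(s.quantile(0.25)) if s.size else float("nan"),
            "score_q3": float(s.quantile(0.75)) if s.size else float("nan"),
        }
        if labels is not None:
            lab = labels[s.index]
            if lab.nunique() == 2:
                res = roc_auc(s.to_numpy(), lab.to_numpy())
                entry["auc"] = res.auc
                entry["oriented_auc"] = res.oriented_auc
                x0 = s[lab == 0].to_numpy()
                x1 = s[lab == 1].to_numpy()
                entry["wilcoxon_p"] = wilcoxon_rank_sum(x0, x1)[1]
                if psa is not None:
                    ps = psa[s.index].dropna()
                    lab_p = labels[ps.index]
                    if lab_p.nunique() == 2 and ps.nunique() > 1:
                        entry["auc_psa"] = roc_auc(ps.to_numpy(), lab_p.to_numpy()).auc
                        entry["delta_auc"] = entry["auc"] - entry["auc_psa"]
                    elif ps.nunique() == 1:
                        entry["auc_psa"] = 0.5
                        entry["delta_auc"] = entry["auc"] - 0.5
        report["subsets"][name] = entry
    return report
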