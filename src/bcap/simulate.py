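"""Seeded synthetic plasma-miRNA qPCR cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
fixed 92-miRNA panel measured in 753 samples across five groups (BPH, LPC,
APC, TRUSbx-benign, TRUSbx-malignant), additive group effects on the Cq
scale, per-sample loading shifts, per-(miRNA, batch) offsets, Gaussian
residual noise, detection dropout above a limit of detection, and clinical
covariates (PSA, DRE, age, prostatectomy pathology, BCR follow-up) drawn to
match the cohort's published summary distributions.  It is a planted-truth
verification harness, not a calibrated disease simulator.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_REFERENCE_PAIR
from .qpcr import (
    ClinicalPathology,
    CqMatrix,
    Dre,
    Finding,
    Group,
    SampleRecord,
    SurvivalRecord,
)
from .ratio import RatioModel

# ---------------------------------------------------------------------------
# Panel: the named miRNAs of the study plus common circulating miRNAs, 92 ids.
_NAMED = [
    "hsa-miR-23a-3p",  # reference pair
    "hsa-miR-93-5p",
    "hsa-miR-375",  # bCaP numerator / strongest upregulated
    "hsa-miR-33a-5p",  # bCaP numerator
    "hsa-miR-16-5p",  # bCaP denominator
    "hsa-miR-409-3p",  # bCaP denominator
    "hsa-miR-146a-5p",  # top downregulated in APC
    "hsa-miR-376c-3p",
    "hsa-miR-410-3p",
    "hsa-miR-154-5p",
    "hsa-miR-130a-3p",
    "hsa-miR-26a-5p",  # top upregulated in APC
    "hsa-miR-142-3p",
    "hsa-miR-451a",
    "hsa-miR-215-5p",
    "hsa-miR-122-5p",
    "hsa-miR-29a-3p",
    "hsa-miR-23b-3p",
    "hsa-miR-140-5p",
    "hsa-miR-376a-3p",
    "hsa-miR-20a-5p",
    "hsa-miR-99a-5p",
    "hsa-miR-19a-3p",
    "hsa-miR-16-2-3p",
    "hsa-miR-17-3p",
]
_FILLER = [
    "hsa-let-7a-5p", "hsa-let-7b-5p", "hsa-let-7c-5p", "hsa-let-7d-5p",
    "hsa-let-7e-5p", "hsa-let-7f-5p", "hsa-let-7g-5p", "hsa-let-7i-5p",
    "hsa-miR-103a-3p", "hsa-miR-106a-5p", "hsa-miR-106b-5p", "hsa-miR-107",
    "hsa-miR-10b-5p", "hsa-miR-125a-5p", "hsa-miR-125b-5p", "hsa-miR-126-3p",
    "hsa-miR-128-3p", "hsa-miR-133a-3p", "hsa-miR-133b", "hsa-miR-134-5p",
    "hsa-miR-141-3p", "hsa-miR-143-3p", "hsa-miR-145-5p", "hsa-miR-148a-3p",
    "hsa-miR-150-5p", "hsa-miR-155-5p", "hsa-miR-15a-5p", "hsa-miR-15b-5p",
    "hsa-miR-181a-5p", "hsa-miR-182-5p", "hsa-miR-183-5p", "hsa-miR-18a-5p",
    "hsa-miR-191-5p", "hsa-miR-192-5p", "hsa-miR-193a-5p", "hsa-miR-194-5p",
    "hsa-miR-195-5p", "hsa-miR-196a-5p", "hsa-miR-199a-3p", "hsa-miR-19b-3p",
    "hsa-miR-200a-3p", "hsa-miR-200b-3p", "hsa-miR-200c-3p", "hsa-miR-205-5p",
    "hsa-miR-20b-5p", "hsa-miR-21-5p", "hsa-miR-210-3p", "hsa-miR-218-5p",
    "hsa-miR-221-3p", "hsa-miR-222-3p", "hsa-miR-223-3p", "hsa-miR-224-5p",
    "hsa-miR-24-3p", "hsa-miR-25-3p", "hsa-miR-27a-3p", "hsa-miR-27b-3p",
    "hsa-miR-30a-5p", "hsa-miR-30c-5p", "hsa-miR-31-5p", "hsa-miR-342-3p",
    "hsa-miR-34a-5p", "hsa-miR-423-5p", "hsa-miR-425-5p", "hsa-miR-486-5p",
    "hsa-miR-92a-3p", "hsa-miR-99b-5p", "hsa-miR-660-5p",
]
DEFAULT_PANEL: list[str] = _NAMED + _FILLER
assert len(DEFAULT_PANEL) == 92 and len(set(DEFAULT_PANEL)) == 92

DEFAULT_GROUP_SIZES: dict[Group, int] = {
    Group.BPH: 144,
    Group.LPC: 407,
    Group.APC: 57,
    Group.TRUSBX_BENIGN: 63,
    Group.TRUSBX_MALIGNANT: 82,
}

# Published fold changes, APC relative to BPH and to LPC (signed linear scale).
PUBLISHED_APC_FOLDS: dict[str, tuple[float, float]] = {
    "hsa-miR-146a-5p": (-1.73, -1.82),
    "hsa-miR-376c-3p": (-1.64, -1.71),
    "hsa-miR-410-3p": (-1.59, -1.65),
    "hsa-miR-154-5p": (-1.51, -1.69),
    "hsa-miR-130a-3p": (-1.48, -1.37),
    "hsa-miR-375": (3.70, 3.27),
    "hsa-miR-26a-5p": (1.89, 2.55),
    "hsa-miR-142-3p": (1.89, 2.76),
    "hsa-miR-451a": (1.84, 3.33),
    "hsa-miR-215-5p": (1.75, 1.82),
}

BCAP_MODEL = RatioModel(
    numerator=("hsa-miR-375", "hsa-miR-33a-5p"),
    denominator=("hsa-miR-16-5p", "hsa-miR-409-3p"),
)

PSA_MEDIANS: dict[Group, float] = {
    Group.BPH: 4.1,
    Group.LPC: 11.40,
    Group.APC: 78.0,
    Group.TRUSBX_BENIGN: 8.4,
    Group.TRUSBX_MALIGNANT: 8.6,
}
_PSA_LOG_SD: dict[Group, float] = {
    Group.BPH: 1.0,
    Group.LPC: 0.55,
    Group.APC: 1.1,
    Group.TRUSBX_BENIGN: 0.5,
    Group.TRUSBX_MALIGNANT: 0.7,
}
_AGE_MEDIAN: dict[Group, float] = {
    Group.BPH: 70, Group.LPC: 64, Group.APC: 78,
    Group.TRUSBX_BENIGN: 66, Group.TRUSBX_MALIGNANT: 68,
}
_AGE_RANGE: dict[Group, tuple[float, float]] = {
    Group.BPH: (46, 87), Group.LPC: (36, 77), Group.APC: (47, 86),
    Group.TRUSBX_BENIGN: (43, 80), Group.TRUSBX_MALIGNANT: (43, 80),
}
DRE_POSITIVE_RATE = {Group.TRUSBX_BENIGN: 0.222, Group.TRUSBX_MALIGNANT: 0.549}
DRE_UNKNOWN_RATE = {Group.TRUSBX_BENIGN: 0.111, Group.TRUSBX_MALIGNANT: 0.085}
# Prostatectomy pathology frequencies of the LPC arm (T3 fraction, grade
# groups 1-5, SM+ rate); SVI/ECE/LNI rates are typical RP-series values.
_LPC_T3_RATE = 0.322
_LPC_GGG_PROBS = [0.366, 0.462, 0.010, 0.128, 0.034]
_LPC_SM_POS = 0.30
_LPC_SVI_POS = 0.10
_LPC_ECE_POS = 0.25
_LPC_LNI_POS = 0.03
_GGG_TO_GLEASON = {1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}


def signed_fold_to_ddcq(fold: float, scale: str = "linear") -> float:
    """Convert a published fold change to a ddCq (log2) planted effect.

    ``linear``: the printed value is a signed linear fold, ddCq =
    sign * log2(|fold|).  ``log2``: the printed value already is a ddCq.
    """
    if scale == "linear":
        return math.copysign(math.log2(abs(fold)), fold)
    if scale == "log2":
        return float(fold)
    raise ValueError(f"unknown fold scale {scale!r}")


def default_planted_effects(
    fold_scale: str = "linear", quartet_effect: float = 1.5
) -> dict[str, dict[Group, float]]:
    """Planted per-group ddCq effects (relative to the BPH/benign baseline).

    The ten published APC-dysregulated miRNAs get their printed APC-vs-BPH
    magnitudes, with LPC effects chosen so the LPC-vs-APC contrast matches
    its printed column too.  The bCaP quartet gets a +/-``quartet_effect``
    dCq signal in malignant TRUSbx samples.  The reference pair is planted
    with zero effect everywhere.
    """
    effects: dict[str, dict[Group, float]] = {}
    for mirna, (fold_bph, fold_lpc) in PUBLISHED_APC_FOLDS.items():
        apc = signed_fold_to_ddcq(fold_bph, fold_scale)
        lpc = apc - signed_fold_to_ddcq(fold_lpc, fold_scale)
        effects[mirna] = {Group.APC: apc, Group.LPC: lpc}
    for mirna in BCAP_MODEL.numerator:
        effects.setdefault(mirna, {})[Group.TRUSBX_MALIGNANT] = quartet_effect
    for mirna in BCAP_MODEL.denominator:
        effects.setdefault(mirna, {})[Group.TRUSBX_MALIGNANT] = -quartet_effect
    for mirna in DEFAULT_REFERENCE_PAIR:
        effects[mirna] = {}
    return effects


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort (defaults match the cohort
    summary table and the planted-effect table)."""

    group_sizes: dict[Group, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    panel: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL))
    baseline_mean: float = 27.0  # mean Cq across the panel
    baseline_sd: float = 3.0  # spread of per-miRNA baselines
    sigma: float = 0.5  # residual noise of planted-effect miRNAs, Cq cycles
    sigma_reference: float = 0.2  # residual noise of the planted stable pair
    filler_sigma_range: tuple[float, float] = (0.6, 1.2)  # unlisted miRNAs
    # carry heterogeneous inter-individual variability, as real panels do
    tau: float = 1.0  # per-sample loading-shift sd
    group_wobble_sd: float = 0.15  # per-(filler miRNA, recruitment arm) drift:
    # no unlisted gene is perfectly group-stable; planted miRNAs follow their
    # effect table exactly and the reference pair is drift-free by definition
    n_batches: int = 3
    batch_sd: float = 0.5  # per-(miRNA, batch) offset sd
    lod_cq: float = 37.0
    fold_scale: str = "linear"
    quartet_effect: float = 1.5
    planted_effects: dict[str, dict[Group, float]] | None = None
    psa_high_effects: dict[str, float] = field(
        default_factory=lambda: {"hsa-miR-375": math.log2(1.49)}
    )
    bcr_log_hr: dict[str, float] = field(default_factory=lambda: {"hsa-miR-375": 0.5})
    bcr_base_rate: float = 0.0115  # events per month
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.planted_effects is None:
            self.planted_effects = default_planted_effects(
                self.fold_scale, self.quartet_effect
            )
        for ref in DEFAULT_REFERENCE_PAIR:
            if any(self.planted_effects.get(ref, {}).values()):
                raise ValueError("planted reference pair must have zero group effect")


@dataclass
class GroundTruth:
    planted_effects: dict[str, dict[Group, float]]
    reference_pair: tuple[str, str]
    quartet_model: RatioModel
    psa_high_effects: dict[str, float]
    bcr_log_hr: dict[str, float]
    planted_de_mirnas: list[str] = field(default_factory=lambda: list(PUBLISHED_APC_FOLDS))


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[CqMatrix, list[SampleRecord], GroundTruth]:
    """Draw a full synthetic cohort: Cq matrix, annotation, ground truth.

    Cq(g, j) = baseline_g - effect_g(group_j) + batch_offset(g, b_j)
    + loading_j + Normal(0, sigma_g); cells above the LOD become missing.
    Fully reproducible: the same (config, seed) gives bit-identical output.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = list(config.panel)
    n_mir = len(panel)
    groups: list[Group] = []
    for g, n in config.group_sizes.items():
        groups.extend([Group(g)] * n)
    n = len(groups)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # per-miRNA baselines: named (planted/reference) miRNAs sit safely below
    # the LOD; filler baselines spread wider so a few show dropout
    baselines = np.empty(n_mir)
    named = set(_NAMED)
    for i, mirna in enumerate(panel):
        if mirna in named:
            baselines[i] = 23.0 + 4.0 * (zlib.crc32(mirna.encode()) % 97) / 97.0
        else:
            baselines[i] = np.clip(
                rng.normal(config.baseline_mean + 1.5, config.baseline_sd), 21.0, 35.5
            )

    batch_labels = rng.integers(0, config.n_batches, size=n)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(n_mir, config.n_batches))
    loading = rng.normal(0.0, config.tau, size=n)

    gi = {m: i for i, m in enumerate(panel)}
    lo, hi = config.filler_sigma_range
    sigma_vec = rng.uniform(lo, hi, size=n_mir)
    for mirna in config.planted_effects:
        if mirna in gi:
            sigma_vec[gi[mirna]] = config.sigma
    for ref in DEFAULT_REFERENCE_PAIR:
        if ref in panel:
            sigma_vec[panel.index(ref)] = config.sigma_reference

    effect = np.zeros((n_mir, n))
    for mirna, per_group in config.planted_effects.items():
        if mirna not in gi:
            continue
        for g, e in per_group.items():
            cols = [j for j, grp in enumerate(groups) if grp == Group(g)]
            effect[gi[mirna], cols] = e
    # biological drift of the unlisted (filler) miRNAs between recruitment
    # arms; the two TRUSbx outcomes are one arm, so drift never mimics the
    # planted biopsy-outcome signal
    arms = {
        Group.BPH: 0,
        Group.LPC: 1,
        Group.APC: 2,
        Group.TRUSBX_BENIGN: 3,
        Group.TRUSBX_MALIGNANT: 3,
    }
    wobble = rng.normal(0.0, config.group_wobble_sd, size=(n_mir, 4))
    for mirna in config.planted_effects:
        if mirna in gi:
            wobble[gi[mirna], :] = 0.0
    acodes = np.array([arms[grp] for grp in groups])
    effect = effect + wobble[:, acodes]

    noise = rng.normal(0.0, 1.0, size=(n_mir, n)) * sigma_vec[:, None]
    cq_vals = (
        baselines[:, None]
        - effect
        + batch_offsets[:, batch_labels]
        + loading[None, :]
        + noise
    )

    # clinical covariates
    psa = np.empty(n)
    age = np.empty(n)
    for g in config.group_sizes:
        cols = np.array([j for j, grp in enumerate(groups) if grp == Group(g)])
        psa[cols] = np.exp(
            rng.normal(math.log(PSA_MEDIANS[Group(g)]), _PSA_LOG_SD[Group(g)], cols.size)
        )
        lo, hi = _AGE_RANGE[Group(g)]
        age[cols] = np.clip(
            rng.normal(_AGE_MEDIAN[Group(g)], (hi - lo) / 5.0, cols.size), lo, hi
        )
    psa = np.clip(psa, 0.2, 2000.0)

    # PSA-stratum expression effects in LPC (applied on the Cq scale)
    for mirna, e in config.psa_high_effects.items():
        if mirna not in gi:
            continue
        cols = [j for j, grp in enumerate(groups) if grp == Group.LPC and psa[j] > 10]
        cq_vals[gi[mirna], cols] -= e

    values = pd.DataFrame(cq_vals, index=panel, columns=sample_ids)
    values[values > config.lod_cq] = np.nan
    cq = CqMatrix(values)

    # realized dCq of the BCR-hazard miRNAs (for the survival generator)
    ref_mean = (
        values.loc[DEFAULT_REFERENCE_PAIR[0]] + values.loc[DEFAULT_REFERENCE_PAIR[1]]
    ) / 2.0

    records: list[SampleRecord] = []
    for j, (sid, grp) in enumerate(zip(sample_ids, groups)):
        psa_j: float | None = float(round(psa[j], 2))
        if grp == Group.BPH and rng.random() < 0.069:
            psa_j = None  # unknown PSA occurs only in the BPH arm

        dre = Dre.UNKNOWN
        if grp in DRE_POSITIVE_RATE:
            # printed positive rates are over all samples incl. unknowns
            if rng.random() >= DRE_UNKNOWN_RATE[grp]:
                p_pos = DRE_POSITIVE_RATE[grp] / (1.0 - DRE_UNKNOWN_RATE[grp])
                dre = Dre.POSITIVE if rng.random() < p_pos else Dre.NEGATIVE

        pathology = None
        survival = None
        if grp == Group.LPC:
            ggg = int(rng.choice([1, 2, 3, 4, 5], p=_LPC_GGG_PROBS))
            gp, gs = _GGG_TO_GLEASON[ggg]
            pathology = ClinicalPathology(
                psa_at_rp=psa_j,
                gleason_primary=gp,
                gleason_secondary=gs,
                t_stage="T3" if rng.random() < _LPC_T3_RATE else "T2",
                gleason_grade_group=ggg,
                sm=Finding.POSITIVE if rng.random() < _LPC_SM_POS else Finding.NEGATIVE,
                svi=Finding.POSITIVE if rng.random() < _LPC_SVI_POS else Finding.NEGATIVE,
                ece=Finding.POSITIVE if rng.random() < _LPC_ECE_POS else Finding.NEGATIVE,
                lni=Finding.POSITIVE if rng.random() < _LPC_LNI_POS else Finding.NEGATIVE,
            )
            log_rel_hazard = 0.0
            for mirna, b in config.bcr_log_hr.items():
                if mirna in gi:
                    dcq = ref_mean[sid] - values.at[mirna, sid]
                    if np.isfinite(dcq):
                        log_rel_hazard += b * (dcq - 0.0)
            rate = config.bcr_base_rate * math.exp(log_rel_hazard)
            t_event = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            t_censor = rng.uniform(12.0, 120.0)
            survival = SurvivalRecord(
                bcr_event=bool(t_event < t_censor),
                time_months=float(max(round(min(t_event, t_censor), 2), 0.1)),
            )

        records.append(
            SampleRecord(
                sample_id=sid,
                group=grp,
                batch=f"B{batch_labels[j] + 1}",
                psa=psa_j,
                dre=dre,
                age=float(round(age[j], 1)),
                pathology=pathology,
                survival=survival,
            )
        )

    truth = GroundTruth(
        planted_effects=config.planted_effects,
        reference_pair=DEFAULT_REFERENCE_PAIR,
        quartet_model=BCAP_MODEL,
        psa_high_effects=dict(config.psa_high_effects),
        bcr_log_hr=dict(config.bcr_log_hr),
    )
    return cq, records, truth
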