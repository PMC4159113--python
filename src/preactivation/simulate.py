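"""Synthetic expression experiments and patient cohorts with known truth.

Two generators cover the pipeline's two workflows:

``simulate_cellline_experiment``
    A two-genotype (differentiated / de-differentiated) × three-treatment
    (vehicle / oxidant / inhibitor) replicated design with planted gene
    programs: oxidant-induced sets per genotype with a controlled common
    core, a preactivated set (induced by oxidant in differentiated cells
    and already up at baseline in de-differentiated cells), baseline up-
    and down-regulated programs, an inhibitor-dependent program, and a
    reference target list with controlled overlaps — so every set
    construction and enrichment test has an exact ground truth.

``simulate_cohort``
    Patient samples with a latent pathway-activity variable that loads on
    the signature genes, drives an exponential survival hazard, and lowers
    the probability of therapy response through a logistic model.

Expression is Gaussian on the log2 scale with additive effects; survival
is exponential with administrative censoring; response is Bernoulli. These
are the simplest models carrying exactly the structure the downstream
analyses assume, and are documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet
from .survival import ResponseRecord, SurvivalRecord

__all__ = [
    "CellLineSimParams",
    "CohortSimParams",
    "simulate_cellline_experiment",
    "simulate_cohort",
]

GENOTYPES = ("differentiated", "de-differentiated")
TREATMENTS = ("vehicle", "oxidant", "inhibitor")


@dataclass(frozen=True)
class CellLineSimParams:
    """Sizes, effect and noise parameters for the cell-line experiment.

    The planted set sizes default to the gene counts of the study design
    this generator emulates: 181 / 170 oxidant-induced genes per genotype
    with 44 in common, 54 preactivated of which 38 uniquely induced in the
    differentiated genotype, 847 genes up and 847 down at baseline in the
    de-differentiated genotype (1,694 differential in total), a 500-gene
    inhibitor-dependent program, and a 1,013-gene reference target list
    with 142 members inside the baseline-up program, 7 of them
    preactivated, and 58 inhibitor-responsive.
    """

    n_genes: int = 10_000
    replicates: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.3
    ros_induced_diff: int = 181
    ros_induced_dediff: int = 170
    common_induced: int = 44
    preactivated: int = 54
    uniquely_induced: int = 38
    dediff_up_total: int = 847
    dediff_down_total: int = 847
    perk_dependent: int = 500
    reference_target_total: int = 1013
    reference_up_in_dediff: int = 142
    reference_in_preactivated: int = 7
    perk_responsive_targets: int = 58
    induction_delta: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        p = self
        if p.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if p.noise_sd < 0 or p.baseline_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if p.common_induced > min(p.ros_induced_diff, p.ros_induced_dediff):
            raise ValueError("common_induced exceeds an induced-set size")
        if p.preactivated > min(p.ros_induced_diff, p.dediff_up_total):
            raise ValueError("preactivated exceeds a containing set size")
        if p.uniquely_induced > p.preactivated:
            raise ValueError("uniquely_induced exceeds preactivated")
        if p.preactivated - p.uniquely_induced > p.common_induced:
            raise ValueError(
                "preactivated ∩ induced_dediff (preactivated − uniquely_induced) "
                "exceeds common_induced"
            )
        if p.reference_in_preactivated > min(p.preactivated, p.reference_up_in_dediff):
            raise ValueError("reference_in_preactivated too large")
        if p.reference_up_in_dediff > min(p.dediff_up_total, p.reference_target_total):
            raise ValueError("reference_up_in_dediff too large")
        if p.perk_responsive_targets > min(p.reference_up_in_dediff, p.perk_dependent):
            raise ValueError("perk_responsive_targets too large")
        if (p.dediff_up_total - p.preactivated
                - (p.reference_up_in_dediff - p.reference_in_preactivated)) < 0:
            raise ValueError(
                "dediff_up_total too small for the preactivated and "
                "reference-target blocks it must contain"
            )
        if self._total_planted() > p.n_genes:
            raise ValueError(
                f"planted blocks need {self._total_planted()} genes but "
                f"n_genes={p.n_genes}"
            )

    def _total_planted(self) -> int:
        p = self
        pre_in_common = p.preactivated - p.uniquely_induced
        return (
            p.ros_induced_diff                      # all induced-diff genes
            + (p.ros_induced_dediff - p.common_induced)  # induced-dediff only
            + (p.dediff_up_total - p.preactivated)  # baseline-up, not preactivated
            + p.dediff_down_total
            + (p.reference_target_total - p.reference_up_in_dediff)
            + (p.perk_dependent - p.perk_responsive_targets)
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_cellline_experiment(
    params: CellLineSimParams = CellLineSimParams(),
) -> tuple[ExpressionMatrix, dict[str, GeneSet]]:
    """Simulate the replicated genotype × treatment experiment.

    Returns the log2 expression matrix (with genotype / treatment /
    replicate metadata) and the planted truth as named gene sets:
    ``induced_differentiated``, ``induced_dedifferentiated``,
    ``common_induced``, ``preactivated``, ``uniquely_induced``,
    ``dediff_up``, ``dediff_down``, ``differential``, ``perk_dependent``,
    ``reference_targets`` and ``reference_up_in_dediff``.

    Deterministic for a given seed.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    genes = np.array(_gene_ids(p.n_genes))
    pool = rng.permutation(p.n_genes)

    cursor = 0

    def carve(size: int) -> np.ndarray:
        nonlocal cursor
        block = pool[cursor:cursor + size]
        cursor += size
        return block

    pre_in_common = p.preactivated - p.uniquely_induced
    common_only = p.common_induced - pre_in_common

    blk_pre_common = carve(pre_in_common)      # preactivated ∩ common core
    blk_common_only = carve(common_only)       # common core, not preactivated
    blk_pre_only = carve(p.uniquely_induced)   # preactivated, induced in diff only
    blk_diff_only = carve(
        p.ros_induced_diff - p.common_induced - p.uniquely_induced
    )
    blk_dediff_only = carve(p.ros_induced_dediff - p.common_induced)
    n_ref_up_rest = p.reference_up_in_dediff - p.reference_in_preactivated
    blk_up_ref = carve(n_ref_up_rest)          # baseline-up reference targets
    blk_up_plain = carve(
        p.dediff_up_total - p.preactivated - n_ref_up_rest
    )
    blk_down = carve(p.dediff_down_total)
    blk_ref_only = carve(p.reference_target_total - p.reference_up_in_dediff)
    blk_perk_only = carve(p.perk_dependent - p.perk_responsive_targets)

    induced_diff = np.concatenate(
        [blk_pre_common, blk_common_only, blk_pre_only, blk_diff_only]
    )
    induced_dediff = np.concatenate(
        [blk_pre_common, blk_common_only, blk_dediff_only]
    )
    preactivated = np.concatenate([blk_pre_common, blk_pre_only])
    dediff_up = np.concatenate([preactivated, blk_up_ref, blk_up_plain])
    ref_in_pre = preactivated[: p.reference_in_preactivated]
    ref_up = np.concatenate([ref_in_pre, blk_up_ref])
    reference = np.concatenate([ref_up, blk_ref_only])
    perk_targets = ref_up[: p.perk_responsive_targets]
    perk_set = np.concatenate([perk_targets, blk_perk_only])

    baseline = rng.normal(p.baseline_mean, p.baseline_sd, size=p.n_genes)

    effect_up = np.zeros(p.n_genes)
    effect_up[dediff_up] = p.induction_delta
    effect_up[blk_down] = -p.induction_delta
    induce_diff_vec = np.zeros(p.n_genes)
    induce_diff_vec[induced_diff] = p.induction_delta
    induce_dediff_vec = np.zeros(p.n_genes)
    induce_dediff_vec[induced_dediff] = p.induction_delta
    perk_vec = np.zeros(p.n_genes)
    perk_vec[perk_set] = -p.induction_delta

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            mean = baseline.copy()
            if genotype == "de-differentiated":
                mean += effect_up
                if treatment == "oxidant":
                    mean += induce_dediff_vec
                elif treatment == "inhibitor":
                    mean += perk_vec
            else:
                if treatment == "oxidant":
                    mean += induce_diff_vec
            for r in range(1, p.replicates + 1):
                short = "dediff" if genotype == "de-differentiated" else "diff"
                sid = f"{short}_{treatment}_r{r}"
                noise = rng.normal(0.0, p.noise_sd, size=p.n_genes) if p.noise_sd else 0.0
                columns[sid] = mean + noise
                meta_rows.append(
                    {"sample_id": sid, "genotype": genotype,
                     "treatment": treatment, "replicate": r}
                )

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    mat = ExpressionMatrix(values, meta)

    def gs(name: str, idx: np.ndarray) -> GeneSet:
        return GeneSet(name=name, members=frozenset(genes[idx]))

    differential = np.concatenate([dediff_up, blk_down])
    truth = {
        "induced_differentiated": gs("induced_differentiated", induced_diff),
        "induced_dedifferentiated": gs("induced_dedifferentiated", induced_dediff),
        "common_induced": gs("common_induced",
                             np.concatenate([blk_pre_common, blk_common_only])),
        "preactivated": gs("preactivated", preactivated),
        "uniquely_induced": gs("uniquely_induced", blk_pre_only),
        "dediff_up": gs("dediff_up", dediff_up),
        "dediff_down": gs("dediff_down", blk_down),
        "differential": gs("differential", differential),
        "perk_dependent": gs("perk_dependent", perk_set),
        "reference_targets": gs("reference_targets", reference),
        "reference_up_in_dediff": gs("reference_up_in_dediff", ref_up),
    }
    return mat, truth


@dataclass(frozen=True)
class CohortSimParams:
    """Latent-activity cohort: expression, survival and response models.

    Each sample carries an activity a_i ~ N(0, 1).  Signature genes get
    expression μ_g + β·a_i + ε with ε ~ N(0, noise_sd); other genes lack
    the activity term.  Survival time is Exponential with rate
    λ0·exp(γ·a_i), administratively censored at C; therapy response is
    Bernoulli with P(responder) = logistic(α − κ·a_i), responders split
    evenly between complete and partial response.
    """

    n_samples: int = 200
    n_genes: int = 5_000
    signature_size: int = 500
    beta: float = 0.8
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    hazard_baseline: float = 0.05
    log_hazard_ratio: float = float(np.log(2.5))
    censor_time: float = 60.0
    response_alpha: float = 1.0
    response_kappa: float = 1.5
    signature_genes: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature_genes is not None:
            sig = tuple(self.signature_genes)
            if len(set(sig)) != len(sig):
                raise ValueError("signature_genes contains duplicates")
            object.__setattr__(self, "signature_genes", sig)
            object.__setattr__(self, "signature_size", len(sig))
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size exceeds n_genes")
        if self.hazard_baseline <= 0 or self.censor_time <= 0:
            raise ValueError("rates and censoring time must be positive")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def simulate_cohort(
    params: CohortSimParams = CohortSimParams(),
) -> tuple[ExpressionMatrix, list[SurvivalRecord], list[ResponseRecord], pd.Series]:
    """Simulate a patient cohort driven by a latent pathway activity.

    Returns the cohort expression matrix (metadata carries time, event and
    response), survival records, response records (stratum unset — filled
    by the analysis), and the true per-sample activities.  The true
    signature is available as ``matrix.values.index[:signature_size]`` or
    via ``params.signature_genes``; a GeneSet is included in the matrix
    metadata attrs for convenience.  Deterministic for a given seed.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    if p.signature_genes is not None:
        sig_genes = list(p.signature_genes)
        filler = [f"C{i:05d}" for i in range(p.n_genes)]
        filler = [g for g in filler if g not in set(sig_genes)]
        genes = sig_genes + filler[: p.n_genes - len(sig_genes)]
    else:
        genes = [f"C{i:05d}" for i in range(p.n_genes)]
        sig_genes = genes[: p.signature_size]
    samples = [f"P{i:04d}" for i in range(p.n_samples)]

    activity = rng.normal(0.0, 1.0, size=p.n_samples)
    baseline = rng.normal(p.baseline_mean, p.baseline_sd, size=p.n_genes)
    vals = np.tile(baseline[:, None], (1, p.n_samples))
    vals[: len(sig_genes), :] += p.beta * activity[None, :]
    if p.noise_sd:
        vals += rng.normal(0.0, p.noise_sd, size=vals.shape)

    rates = p.hazard_baseline * np.exp(p.log_hazard_ratio * activity)
    raw_times = rng.exponential(1.0 / rates)
    event = raw_times <= p.censor_time
    times = np.minimum(raw_times, p.censor_time)

    p_resp = 1.0 / (1.0 + np.exp(-(p.response_alpha - p.response_kappa * activity)))
    responder = rng.random(p.n_samples) < p_resp
    complete = rng.random(p.n_samples) < 0.5

    meta = pd.DataFrame(
        {
            "time": times,
            "event": event,
            "response": [
                ("complete" if c else "partial") if r else "stable_progressive"
                for r, c in zip(responder, complete)
            ],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    values = pd.DataFrame(vals, index=pd.Index(genes), columns=samples)
    mat = ExpressionMatrix(values, meta)

    surv = [
        SurvivalRecord(sample_id=s, time=float(t), event=bool(e))
        for s, t, e in zip(samples, times, event)
    ]
    resp = [
        ResponseRecord(sample_id=s, category=str(meta.loc[s, "response"]))
        for s in samples
    ]
    activities = pd.Series(activity, index=samples, name="activity")
    return mat, surv, resp, activities


def true_signature(params: CohortSimParams) -> GeneSet:
    """The gene set carrying the activity loading in :func:`simulate_cohort`."""
    if params.signature_genes is not None:
        members = frozenset(params.signature_genes)
    else:
        members = frozenset(f"C{i:05d}" for i in range(params.signature_size))
    return GeneSet(name="true_signature", members=members)
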