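"""End-to-end workflows: preactivation analysis and cohort signature analysis.

Both entry points consume in-memory objects, return a JSON-serializable
report dict, and optionally write the standard artifacts (GMT gene sets,
TSV tables, a JSON summary and a manifest) into an output directory.
Reports contain no timestamps, so identical inputs yield byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import (
    ContrastSpec,
    differential_set,
    log2_fold_changes,
    preactivated_set,
    uniquely_induced_set,
    up_regulated_set,
)
from .io import ExpressionMatrix, GeneSet, write_expression_tsv, write_gmt
from .scoring import ScoreTable, mc_correlation_pvalue, score_cohort, spearman_rho, stratify
from .setstats import enrichment_test, overlap_test
from .survival import (
    ResponseRecord,
    SurvivalRecord,
    km_curve,
    logrank_test,
    response_fraction,
)

__all__ = [
    "PreactivationConfig",
    "CohortConfig",
    "run_preactivation",
    "run_cohort_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class PreactivationConfig:
    """Column names, factor levels and thresholds for the arm resolution."""

    genotype_col: str = "genotype"
    treatment_col: str = "treatment"
    differentiated: str = "differentiated"
    dedifferentiated: str = "de-differentiated"
    vehicle: str = "vehicle"
    oxidant: str = "oxidant"
    fc_threshold: float = 2.0
    universe: GeneSet | None = None  # default: all measured genes
    target_sets: tuple[GeneSet, ...] = ()
    out_dir: Path | None = None


def _resolve_arm(
    meta: pd.DataFrame, config: PreactivationConfig, genotype: str, treatment: str
) -> list[str]:
    for col in (config.genotype_col, config.treatment_col):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    mask = (meta[config.genotype_col] == genotype) & (
        meta[config.treatment_col] == treatment
    )
    samples = list(meta.index[mask])
    if not samples:
        raise ValueError(
            f"no samples with {config.genotype_col}={genotype!r} and "
            f"{config.treatment_col}={treatment!r}"
        )
    return samples


def run_preactivation(
    mat: ExpressionMatrix, config: PreactivationConfig | None = None
) -> dict:
    """Full preactivation chain on a genotype × treatment experiment.

    Calls the oxidant-induced set in each genotype, the baseline
    differential sets between genotypes, the common-induced overlap, the
    preactivated set (with its overlap statistics), the uniquely-induced
    set, and optional enrichment of the preactivated set in each provided
    target list.  The hypergeometric universe defaults to all measured
    genes.
    """
    config = config or PreactivationConfig()
    if mat.metadata is None:
        raise ValueError("expression matrix has no sample metadata")
    meta = mat.metadata

    arm = {
        (g, t): _resolve_arm(mat.metadata, config, gv, tv)
        for (g, t), (gv, tv) in {
            ("diff", "vehicle"): (config.differentiated, config.vehicle),
            ("diff", "oxidant"): (config.differentiated, config.oxidant),
            ("dediff", "vehicle"): (config.dedifferentiated, config.vehicle),
            ("dediff", "oxidant"): (config.dedifferentiated, config.oxidant),
        }.items()
    }

    fc = config.fc_threshold
    induced_diff = up_regulated_set(
        mat,
        ContrastSpec(arm[("diff", "oxidant")], arm[("diff", "vehicle")], fc),
        name="induced_differentiated",
    )
    induced_dediff = up_regulated_set(
        mat,
        ContrastSpec(arm[("dediff", "oxidant")], arm[("dediff", "vehicle")], fc),
        name="induced_dedifferentiated",
    )
    baseline_contrast = ContrastSpec(
        arm[("dediff", "vehicle")], arm[("diff", "vehicle")], fc
    )
    dediff_up, dediff_down = differential_set(mat, baseline_contrast, name="dediff")
    differential = GeneSet(
        name="differential", members=dediff_up.members | dediff_down.members
    )

    universe = config.universe or GeneSet(
        name="measured_genes", members=frozenset(mat.genes)
    )
    common = overlap_test(induced_diff, induced_dediff, universe)
    common_set = GeneSet(
        name="common_induced", members=induced_diff.members & induced_dediff.members
    )
    preactivated = preactivated_set(induced_diff, dediff_up)
    preactivated_overlap = overlap_test(induced_diff, dediff_up, universe)
    unique = uniquely_induced_set(induced_diff, induced_dediff, preactivated)

    enrichments = {}
    for target in config.target_sets:
        res = enrichment_test(preactivated, target, universe)
        enrichments[target.name] = res.as_dict()

    baseline_fc = log2_fold_changes(mat, baseline_contrast)

    report = {
        "parameters": {
            "fc_threshold": fc,
            "universe_size": len(universe),
            "genotype_col": config.genotype_col,
            "treatment_col": config.treatment_col,
        },
        "counts": {
            "induced_differentiated": len(induced_diff),
            "induced_dedifferentiated": len(induced_dediff),
            "common_induced": common.k,
            "preactivated": len(preactivated),
            "uniquely_induced": len(unique),
            "dediff_up": len(dediff_up),
            "dediff_down": len(dediff_down),
            "differential": len(differential),
        },
        "common_induced_overlap": common.as_dict(),
        "preactivated_overlap": preactivated_overlap.as_dict(),
        "target_enrichment": enrichments,
        "version": __version__,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sets = [
            induced_diff, induced_dediff, common_set, preactivated, unique,
            dediff_up, dediff_down, differential,
        ]
        write_gmt(sets, out / "preactivation_sets.gmt")
        fc_table = pd.DataFrame({"log2_fc_dediff_vs_diff": baseline_fc})
        fc_table.index.name = "gene_id"
        fc_table.to_csv(out / "baseline_fold_changes.tsv", sep="\t")
        (out / "preactivation_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


@dataclass
class CohortConfig:
    """Scoring, stratification and testing parameters for cohort analysis."""

    fraction: float = 0.15
    reps: int = 1000
    seed: int = 0
    signature_b: GeneSet | None = None  # second signature for correlation
    endpoint_label: str = "survival"
    out_dir: Path | None = None
    plot: bool = False


def run_cohort_analysis(
    cohort: ExpressionMatrix,
    signature: GeneSet,
    config: CohortConfig | None = None,
    survival: Sequence[SurvivalRecord] | None = None,
    response: Sequence[ResponseRecord] | None = None,
) -> dict:
    """Score a cohort, stratify, and compare outcomes between strata.

    Survival and response records may be passed explicitly or derived from
    the cohort metadata (columns ``time``, ``event`` and ``response``).
    Scores and strata depend only on the inputs; the seed affects only the
    Monte Carlo correlation null.
    """
    config = config or CohortConfig()
    table = stratify(score_cohort(cohort, signature), config.fraction)
    strata = table.strata

    meta = cohort.metadata if cohort.metadata is not None else pd.DataFrame()
    if survival is None and {"time", "event"} <= set(meta.columns):
        survival = [
            SurvivalRecord(sample_id=str(s), time=float(meta.loc[s, "time"]),
                           event=bool(meta.loc[s, "event"]))
            for s in meta.index
        ]
    if response is None and "response" in meta.columns:
        response = [
            ResponseRecord(sample_id=str(s), category=str(meta.loc[s, "response"]))
            for s in meta.index
        ]

    report: dict = {
        "parameters": {
            "signature": signature.name,
            "signature_size": len(signature),
            "coverage": table.coverage,
            "fraction": config.fraction,
            "reps": config.reps,
            "seed": config.seed,
            "endpoint": config.endpoint_label,
        },
        "strata_sizes": {
            label: int((strata == label).sum()) for label in ("high", "low", "mid")
        },
        "version": __version__,
    }

    curves: dict[str, list[tuple[float, float]]] = {}
    if survival is not None:
        by_stratum: dict[str, list[SurvivalRecord]] = {"high": [], "low": []}
        lookup = {r.sample_id: r for r in survival}
        for label in ("high", "low"):
            for sid in table.samples_in(label):
                rec = lookup.get(str(sid))
                if rec is not None:
                    by_stratum[label].append(
                        SurvivalRecord(rec.sample_id, rec.time, rec.event, label)
                    )
        stat, p = logrank_test(by_stratum["high"], by_stratum["low"])
        curves = {label: km_curve(recs) for label, recs in by_stratum.items()}
        report["logrank"] = {"chi_square": stat, "p_value": p}
        report["km_final_survival"] = {
            label: curves[label][-1][1] for label in curves
        }

    if response is not None:
        stratum_of = strata.to_dict()
        labeled = [
            ResponseRecord(r.sample_id, r.category, str(stratum_of[r.sample_id]))
            for r in response
            if r.sample_id in stratum_of and stratum_of[r.sample_id] in ("high", "low")
        ]
        report["responder_fraction"] = response_fraction(labeled)

    if config.signature_b is not None:
        scores_b = score_cohort(cohort, config.signature_b)
        rho, p_mc = mc_correlation_pvalue(
            cohort, signature, scores_b, reps=config.reps, seed=config.seed
        )
        report["signature_correlation"] = {
            "signature_b": config.signature_b.name,
            "spearman_rho": rho,
            "mc_p_value": p_mc,
        }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_frame().to_csv(out / "score_table.tsv", sep="\t")
        for label, curve in curves.items():
            pd.DataFrame(curve, columns=["time", "survival"]).to_csv(
                out / f"km_{label}.tsv", sep="\t", index=False
            )
        (out / "cohort_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        if config.plot and curves:
            _plot_km(curves, out / "km_plot.png")
    return report


def _plot_km(curves: dict[str, list[tuple[float, float]]], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in sorted(curves.items()):
        t = [pt[0] for pt in curve]
        s = [pt[1] for pt in curve]
        ax.step(t, s, where="post", label=f"{label} signature")
    ax.set_xlabel("time")
    ax.set_ylabel("survival fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
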