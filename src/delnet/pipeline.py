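"""End-to-end orchestration: simulate -> denoise -> connectivity -> MST -> stats.

``run_pipeline`` drives a whole synthetic cohort through the per-subject
chain, collects the five network outcomes for every subject that passes the
exclusion gates, fits the risk-factor models, and returns a run manifest
that accounts for every subject (analyzed = eligible - sum of exclusions;
each excluded subject carries exactly one primary reason: the first gate it
failed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (RegionSet, ZeroVarianceError, default_region_sets,
                           pearson_matrix, regional_connectivity)
from .denoise import denoise_subject
from .mst import DisconnectedGraphError, kruskal_mst, global_strength, \
    diameter, leaf_fraction
from .stats import OUTCOME_NAMES, run_risk_factor_models
from .synthetic import SimulationConfig, SubjectData, simulate_cohort_subjects

__all__ = [
    "DEFAULT_DETERMINANTS",
    "participant_flow",
    "flow_ledger",
    "subject_network_outcomes",
    "cohort_network_outcomes",
    "run_pipeline",
    "PipelineResult",
    "replicate_planted_beta",
]

#: the seven predisposing risk factors entering the models
DEFAULT_DETERMINANTS = ("age", "alcohol_misuse", "mmse", "depression",
                        "barthel", "tia_stroke", "asa_unhealthy")


def participant_flow(eligible: int, exclusions: dict) -> int:
    """Analyzed sample size after applying exclusion counts to ``eligible``."""
    if eligible < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("counts must be non-negative")
    analyzed = eligible - sum(exclusions.values())
    if analyzed < 0:
        raise ValueError("exclusions exceed the eligible count")
    return analyzed


def _auto_region_sets(n_regions: int):
    """Region sets for the regional outcomes at any simulated scale.

    At the full 264-region parcellation the standard PCC / DLPFC sets are
    used; at reduced scale, small synthetic stand-in sets on the first
    regions keep the regional outcomes exercised.
    """
    if n_regions >= 264:
        return default_region_sets()
    if n_regions < 7:
        return None
    return (RegionSet("PCC_synthetic", (1, 2, 3)),
            RegionSet("DLPFC_left_synthetic", (4, 5)),
            RegionSet("DLPFC_right_synthetic", (6, 7)))


def subject_network_outcomes(sub: SubjectData, region_sets=None,
                             **denoise_kwargs):
    """Denoise one subject and compute its network outcomes.

    Returns ``(outcomes_dict, None, qc)`` on success or
    ``(None, reason, qc)`` when a gate or validity rule excludes the
    subject.
    """
    res = denoise_subject(sub.series, sub.motion, sub.wm, sub.csf,
                          sub.global_sig, **denoise_kwargs)
    if not res.passed:
        return None, res.reason, res.qc
    try:
        R = pearson_matrix(res.series)
    except ZeroVarianceError:
        return None, "zero_variance", res.qc
    try:
        tree = kruskal_mst(R)
    except DisconnectedGraphError:
        return None, "disconnected", res.qc
    out = {
        "strength": global_strength(tree),
        "diameter": float(diameter(tree)),
        "leaf_fraction": leaf_fraction(tree),
    }
    if region_sets is not None:
        pcc, dl, dr = region_sets
        out["pcc_dlpfc_left"] = regional_connectivity(res.series, pcc, dl)
        out["pcc_dlpfc_right"] = regional_connectivity(res.series, pcc, dr)
    return out, None, res.qc


def cohort_network_outcomes(config: SimulationConfig,
                            region_sets="auto",
                            **denoise_kwargs):
    """Run every synthetic subject through the chain.

    Returns ``(table, manifest)``: the table holds covariates plus network
    outcomes for analyzed subjects; the manifest records per-subject gate
    results and the exclusion accounting.
    """
    if region_sets == "auto":
        region_sets = _auto_region_sets(config.n_regions)
    rows, subject_log = [], []
    exclusions: dict[str, int] = {}
    for cov_row, sub in simulate_cohort_subjects(config):
        out, reason, qc = subject_network_outcomes(sub, region_sets,
                                                   **denoise_kwargs)
        entry = {"id": sub.subject_id, "excluded_reason": reason, "qc": qc}
        subject_log.append(entry)
        if reason is not None:
            exclusions[reason] = exclusions.get(reason, 0) + 1
            continue
        rows.append({**cov_row.to_dict(), **out})
    table = pd.DataFrame(rows)
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "version": __version__,
        "n_eligible": config.n_subjects,
        "exclusions": exclusions,
        "n_analyzed": len(rows),
        "subjects": subject_log,
    }
    assert manifest["n_analyzed"] == participant_flow(config.n_subjects,
                                                      exclusions)
    return table, manifest


def flow_ledger(manifest: dict) -> pd.DataFrame:
    """Participant-flow table: eligible, each exclusion reason, analyzed."""
    rows = [{"stage": "eligible", "count": manifest["n_eligible"]}]
    for reason, count in sorted(manifest["exclusions"].items()):
        rows.append({"stage": f"excluded:{reason}", "count": count})
    rows.append({"stage": "analyzed", "count": manifest["n_analyzed"]})
    df = pd.DataFrame(rows)
    total = df.loc[df.stage.str.startswith("excluded"), "count"].sum()
    assert manifest["n_analyzed"] + total == manifest["n_eligible"]
    return df


@dataclass
class PipelineResult:
    manifest: dict
    outcomes: pd.DataFrame
    models_individual: pd.DataFrame | None
    models_combined: pd.DataFrame | None


def run_pipeline(config: SimulationConfig,
                 determinants=DEFAULT_DETERMINANTS,
                 out_dir=None,
                 region_sets="auto",
                 **denoise_kwargs) -> PipelineResult:
    """Full run; optionally writes all artifacts with stable filenames.

    When too few subjects survive the gates to support the regressions, the
    stats stage is skipped and the manifest carries an explicit note.
    """
    table, manifest = cohort_network_outcomes(config, region_sets,
                                              **denoise_kwargs)
    n_predictors = len(determinants) + 3
    models_ind = models_comb = None
    if len(table) > n_predictors + 1:
        models_ind = run_risk_factor_models(table, determinants)
        models_comb = run_risk_factor_models(table, determinants,
                                             combined=True)
    else:
        manifest["stats_skipped"] = (
            f"only {len(table)} analyzed subjects for "
            f"{n_predictors} predictors"
        )
    if out_dir is not None:
        from pathlib import Path
        from .io import write_manifest_json
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "outcomes.csv", index=False)
        flow_ledger(manifest).to_csv(out / "flow.csv", index=False)
        write_manifest_json(out / "manifest.json", manifest)
        if models_ind is not None:
            models_ind.to_csv(out / "models_individual.csv", index=False)
            models_comb.to_csv(out / "models_combined.csv", index=False)
    return PipelineResult(manifest, table, models_ind, models_comb)


def replicate_planted_beta(config: SimulationConfig, n_replicates: int,
                           base_seed: int = 0,
                           outcome: str = "strength") -> pd.DataFrame:
    """Standardized beta-hat and raw p of the planted covariate per replicate.

    Re-runs the simulate -> denoise -> connectivity -> MST -> regression
    chain ``n_replicates`` times with derived seeds and fits
    ``outcome ~ planted covariate + centre + gender + IQ`` each time.
    Regional outcomes are skipped for speed (they do not enter this model).
    """
    from .stats import ModelSpec, fit_model

    det = config.planted_covariate or "age"
    seeds = (np.random.SeedSequence(base_seed)
             .generate_state(n_replicates, dtype=np.uint32) >> 1)
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=int(seeds[rep]))
        table, manifest = cohort_network_outcomes(cfg, region_sets=None)
        spec = ModelSpec(outcome, (det,))
        res = fit_model(table, spec)
        rows.append({"replicate": rep, "seed": int(seeds[rep]),
                     "n_analyzed": manifest["n_analyzed"],
                     "beta": res.beta_std[det], "p": res.p_values[det]})
    return pd.DataFrame(rows)
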