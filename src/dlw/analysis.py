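"""Cohort-level composition: the four analysis arms and their comparison.

The four arms are the combinations the method-comparison literature on DLW
contrasts:

1. natural (non-normalized) non-Bayesian — classical fits, Coward equation;
2. normalized non-Bayesian — classical fits, space normalization, Schoeller
   equation;
3. independent Bayesian — per-subject MCMC;
4. hierarchical Bayesian — population MCMC, one stratum per sex.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from . import bayes, classical
from .io import AnalysisConfig
from .types import SubjectRecord

logger = logging.getLogger(__name__)

ARMS = ("natural", "normalized", "independent", "hierarchical")
REPORT_PARAMS = ("S", "F", "rCO2", "TEE")


def _classical_rows(subjects, method, normalization, c, arm_name):
    rows = []
    for s in subjects:
        try:
            res = classical.classical_tee(s, method=method, normalization=normalization, c=c)
        except classical.FitError as exc:
            logger.warning("%s arm failed for subject %s: %s", arm_name, s.id, exc)
            continue
        phys_S = res.S_natural if normalization == "none" else {
            "schoeller": c.schoeller_ratio, "iaea": c.iaea_ratio
        }[normalization]
        kin = res.kin
        F = 1.0 - (c.gamma1 * kin.N_H + c.gamma2 * kin.N_O) / s.weight
        rows.append({
            "subject_id": s.id, "sex": s.sex, "arm": arm_name,
            "S": phys_S, "F": F, "rCO2": res.rCO2, "TEE": res.TEE,
            "cv": res.cv, "flags": ";".join(res.flags),
        })
    return rows


def run_four_arm_analysis(subjects: list[SubjectRecord], config: AnalysisConfig | None = None) -> dict:
    """Run all four arms on a cohort and assemble the comparison report.

    Returns a dict with a per-subject table (``per_subject``), per-sex
    median/range summaries (``by_sex``), and Bland-Altman statistics for the
    TEE comparisons between arms (``bland_altman``).  Arms that fail for a
    subject are logged and omitted from that arm only.
    """
    config = config or AnalysisConfig()
    c = config.constants()
    rows: list[dict] = []

    rows += _classical_rows(subjects, config.fit_method, "none", c, "natural")
    rows += _classical_rows(subjects, config.fit_method, config.normalization, c, "normalized")

    for s in subjects:
        try:
            res = bayes.sample_independent(s, cfg=config.mcmc, c=c)
        except Exception as exc:  # pragma: no cover - defensive per-subject isolation
            logger.warning("independent Bayesian arm failed for subject %s: %s", s.id, exc)
            continue
        med = {p: float(np.median(res.stacked(p))) for p in REPORT_PARAMS}
        rows.append({"subject_id": s.id, "sex": s.sex, "arm": "independent",
                     "cv": None, "flags": "", **med})

    hyper = {}
    for sex in ("F", "M"):
        stratum = [s for s in subjects if s.sex == sex]
        if len(stratum) < 3:
            if stratum:
                logger.warning("hierarchical arm skipped for sex %s: fewer than 3 subjects", sex)
            continue
        res = bayes.sample_hierarchical(stratum, cfg=config.mcmc, c=c)
        med_by_param = {p: bayes.subject_medians(res, p) for p in REPORT_PARAMS}
        for i, sid in enumerate(res.subject_ids):
            rows.append({
                "subject_id": sid, "sex": sex, "arm": "hierarchical",
                "cv": None, "flags": "",
                **{p: float(med_by_param[p][i]) for p in REPORT_PARAMS},
            })
        hyper[sex] = {
            "S_g_mean": float(res.stacked("S_g").mean()),
            "S_g_sd": float(res.stacked("S_g").std(ddof=1)),
            "TEE_g_median": float(np.median(res.stacked("TEE_g"))),
        }

    per_subject = pd.DataFrame(rows)

    by_sex: dict = {}
    for sex_label, frame in (("F", per_subject[per_subject.sex == "F"]),
                             ("M", per_subject[per_subject.sex == "M"]),
                             ("combined", per_subject)):
        if frame.empty:
            continue
        by_sex[sex_label] = {}
        for p in REPORT_PARAMS:
            by_sex[sex_label][p] = {}
            for arm in ARMS:
                vals = frame[frame.arm == arm][p].to_numpy(dtype=float)
                if vals.size == 0:
                    continue
                by_sex[sex_label][p][arm] = {
                    "median": float(np.median(vals)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }

    comparisons = {}
    pairs = [("natural", "normalized"), ("normalized", "independent"), ("normalized", "hierarchical")]
    for label, frame in (("combined", per_subject),
                         ("F", per_subject[per_subject.sex == "F"]),
                         ("M", per_subject[per_subject.sex == "M"])):
        for arm_a, arm_b in pairs:
            a = frame[frame.arm == arm_a].set_index("subject_id")["TEE"]
            b = frame[frame.arm == arm_b].set_index("subject_id")["TEE"]
            common = a.index.intersection(b.index)
            if common.size < 3:
                continue
            stats = classical.bland_altman(a.loc[common].to_numpy(), b.loc[common].to_numpy())
            comparisons[f"{arm_b}_vs_{arm_a}[{label}]"] = stats.as_dict()

    return {
        "per_subject": per_subject,
        "by_sex": by_sex,
        "hyperparameters": hyper,
        "bland_altman": comparisons,
    }


def report_to_json_dict(report: dict) -> dict:
    """JSON-serializable view of a four-arm report."""
    out = dict(report)
    out["per_subject"] = report["per_subject"].to_dict(orient="records")
    return out
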