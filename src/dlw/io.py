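"""Reading and writing DLW cohort data and analysis configuration.

The on-disk cohort format is two CSV files:

``measurements.csv``
    One row per enrichment measurement: ``subject_id, isotope, time_days,
    delta_permil`` with isotope coded ``2H`` or ``18O``.

``metadata.csv``
    One row per subject: ``subject_id, sex, weight_kg`` plus, per isotope
    suffix (``_2h`` / ``_18o``): ``dose_g``, ``aliquot_g``, ``dilution_g``,
    ``delta_dd``, ``delta_t`` and ``basal`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .bayes import MCMCConfig
from .constants import ModelConstants
from .types import DosePrep, DomainError, IsotopeCurve, SubjectRecord

logger = logging.getLogger(__name__)

_ISO_SUFFIX = {"2H": "2h", "18O": "18o"}

MEASUREMENTS_FILE = "measurements.csv"
METADATA_FILE = "metadata.csv"
TRUTH_FILE = "truth.csv"


class CohortFormatError(ValueError):
    """The cohort files are malformed; the message carries line numbers."""


def read_cohort(measurements: str | Path, metadata: str | Path) -> list[SubjectRecord]:
    """Load subject records, validating rows and reporting offending lines.

    A subject missing one of the two isotopes is skipped with a warning;
    structurally invalid rows (negative times, unknown isotope codes,
    non-numeric values) abort with a line-numbered error.
    """
    meas = pd.read_csv(measurements)
    meta = pd.read_csv(metadata)
    if meas.empty or meta.empty:
        raise CohortFormatError("empty cohort file")

    problems = []
    for idx, row in meas.iterrows():
        line = idx + 2  # header is line 1
        if row["isotope"] not in _ISO_SUFFIX:
            problems.append(f"line {line}: unknown isotope {row['isotope']!r}")
            continue
        try:
            t = float(row["time_days"])
            float(row["delta_permil"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric time or delta")
            continue
        if t < 0:
            problems.append(f"line {line}: negative time {t}")
    if problems:
        raise CohortFormatError("malformed measurement rows:\n" + "\n".join(problems))

    subjects: list[SubjectRecord] = []
    for _, mrow in meta.iterrows():
        sid = str(mrow["subject_id"])
        rows = meas[meas["subject_id"].astype(str) == sid]
        doses, curves = {}, {}
        try:
            for iso, suf in _ISO_SUFFIX.items():
                iso_rows = rows[rows["isotope"] == iso].sort_values("time_days")
                if iso_rows.empty:
                    raise KeyError(iso)
                doses[iso] = DosePrep(
                    D=float(mrow[f"dose_g_{suf}"]),
                    d=float(mrow[f"aliquot_g_{suf}"]),
                    T=float(mrow[f"dilution_g_{suf}"]),
                    delta_dd=float(mrow[f"delta_dd_{suf}"]),
                    delta_T=float(mrow[f"delta_t_{suf}"]),
                )
                curves[iso] = IsotopeCurve(
                    isotope=iso,
                    times=iso_rows["time_days"].to_numpy(dtype=float),
                    delta_values=iso_rows["delta_permil"].to_numpy(dtype=float),
                    delta_b=float(mrow[f"basal_{suf}"]),
                )
            subjects.append(
                SubjectRecord(
                    id=sid, sex=str(mrow["sex"]), weight=float(mrow["weight_kg"]),
                    doses=doses, curves=curves,
                )
            )
        except KeyError as exc:
            logger.warning("subject %s skipped: missing isotope data %s", sid, exc)
        except DomainError as exc:
            logger.warning("subject %s skipped: %s", sid, exc)
    if not subjects:
        raise CohortFormatError("no valid subjects could be read")
    return subjects


def write_cohort(subjects: list[SubjectRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write a cohort in the two-CSV format; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meas_rows, meta_rows = [], []
    for s in subjects:
        meta: dict = {"subject_id": s.id, "sex": s.sex, "weight_kg": s.weight}
        for iso, suf in _ISO_SUFFIX.items():
            dose, curve = s.doses[iso], s.curves[iso]
            meta.update({
                f"dose_g_{suf}": dose.D,
                f"aliquot_g_{suf}": dose.d,
                f"dilution_g_{suf}": dose.T,
                f"delta_dd_{suf}": dose.delta_dd,
                f"delta_t_{suf}": dose.delta_T,
                f"basal_{suf}": curve.delta_b,
            })
            for t, d in zip(curve.times, curve.delta_values):
                meas_rows.append({
                    "subject_id": s.id, "isotope": iso,
                    "time_days": t, "delta_permil": d,
                })
        meta_rows.append(meta)
    meas_path = out_dir / MEASUREMENTS_FILE
    meta_path = out_dir / METADATA_FILE
    pd.DataFrame(meas_rows).to_csv(meas_path, index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return meas_path, meta_path


def read_cohort_dir(data_dir: str | Path) -> list[SubjectRecord]:
    data_dir = Path(data_dir)
    return read_cohort(data_dir / MEASUREMENTS_FILE, data_dir / METADATA_FILE)


def write_truth(truths, out_dir: str | Path) -> Path:
    """Write the ground-truth table of a synthetic cohort for recovery scoring."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "subject_id": t.id, "sex": t.sex, "weight_kg": t.weight,
            "rCO2": t.phys.rCO2, "S": t.phys.S, "R_W": t.phys.R_W, "F": t.phys.F,
            "N_H": t.kin.N_H, "N_O": t.kin.N_O, "k_H": t.kin.k_H, "k_O": t.kin.k_O,
        }
        for t in truths
    ]
    path = out_dir / TRUTH_FILE
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@dataclass
class AnalysisConfig:
    """Configuration for a full cohort analysis."""

    fractionation_model: str = "schoeller"  # parameterization of rCO2 in the Bayesian model
    fit_method: str = "logarithmic"  # classical curve-fit flavour
    normalization: str = "schoeller"  # space correction of the normalized arm
    rq: float = 0.85
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)

    def constants(self) -> ModelConstants:
        from dataclasses import replace

        c = ModelConstants.for_model(self.fractionation_model)
        return replace(c, rq=self.rq)
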