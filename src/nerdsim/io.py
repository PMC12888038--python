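"""Serialization of parameters, priors, trajectories and cohorts.

Cohorts are written as three CSV files plus a metadata JSON:

* ``assessments.csv`` — long format: patient_id, arm, time_weeks, symptom_score
* ``baseline.csv`` — patient_id, vor_asym_pct, sot_composite,
  primitive_reflex_count, persistent_3mo, phenotype
* ``truth.csv`` — the generating coefficients and injury-signal parameters
  (the ground truth that downstream estimation tries to recover)

CSV dialect: UTF-8, comma-separated, ``.`` decimal, header required; parsing
is header-driven so column order is irrelevant.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigError, DomainError
from .cohort import (
    Biomarkers, Cohort, PatientRecord, persistence_score,
)
from .model import COEFFICIENT_NAMES, InjurySignal, NerdParameters, Trajectory
from .priors import PriorSet

__all__ = [
    "write_json", "read_json", "write_yaml", "read_yaml",
    "parameters_to_file", "parameters_from_file",
    "priors_to_file", "priors_from_file",
    "trajectory_to_csv", "write_cohort", "read_cohort", "run_manifest",
]

_ASSESSMENT_COLS = ["patient_id", "arm", "time_weeks", "symptom_score"]
_BASELINE_COLS = ["patient_id", "vor_asym_pct", "sot_composite",
                  "primitive_reflex_count", "persistent_3mo", "phenotype"]
_TRUTH_COLS = (["patient_id"] + list(COEFFICIENT_NAMES)
               + ["G0", "N0", "severity", "I_kind", "I_magnitude", "I_tau",
                  "CI_kind", "CI_magnitude", "CI_tau"])


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_yaml(obj, path):
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def _dump(obj: dict, path: Union[str, Path]):
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        write_yaml(obj, path)
    else:
        write_json(obj, path)


def _load(path: Union[str, Path]) -> dict:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        return read_yaml(path)
    return read_json(path)


def parameters_to_file(p: NerdParameters, path):
    _dump(p.as_dict(), path)


def parameters_from_file(path) -> NerdParameters:
    return NerdParameters.from_dict(_load(path))


def priors_to_file(priors: PriorSet, path):
    _dump(priors.as_dict(), path)


def priors_from_file(path) -> PriorSet:
    return PriorSet.from_dict(_load(path))


def trajectory_to_csv(traj: Trajectory, path):
    traj.to_frame().to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols, filename: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(f"{filename}: missing column(s) {', '.join(missing)}")


def write_cohort(cohort: Cohort, directory):
    """Write assessments, baseline and truth CSVs plus generation metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        for t, s in zip(p.schedule, p.scores):
            rows.append((p.id, p.arm or "", float(t), float(s)))
    pd.DataFrame(rows, columns=_ASSESSMENT_COLS).to_csv(
        directory / "assessments.csv", index=False)

    base = pd.DataFrame({
        "patient_id": [p.id for p in cohort],
        "vor_asym_pct": [p.biomarkers.vor_asym_pct for p in cohort],
        "sot_composite": [p.biomarkers.sot_composite for p in cohort],
        "primitive_reflex_count": [p.biomarkers.primitive_reflex_count for p in cohort],
        "persistent_3mo": [int(p.persistent_at_3mo) for p in cohort],
        "phenotype": [p.recovery_phenotype for p in cohort],
    })
    base.to_csv(directory / "baseline.csv", index=False)

    truth = pd.DataFrame({
        "patient_id": [p.id for p in cohort],
        **{name: [getattr(p.params, name) for p in cohort] for name in COEFFICIENT_NAMES},
        "G0": [p.params.G0 for p in cohort],
        "N0": [p.params.N0 for p in cohort],
        "severity": [p.severity for p in cohort],
        "I_kind": [p.I.kind for p in cohort],
        "I_magnitude": [p.I.magnitude for p in cohort],
        "I_tau": [p.I.tau if p.I.tau is not None else np.nan for p in cohort],
        "CI_kind": [p.CI.kind for p in cohort],
        "CI_magnitude": [p.CI.magnitude for p in cohort],
        "CI_tau": [p.CI.tau if p.CI.tau is not None else np.nan for p in cohort],
    })
    truth.to_csv(directory / "truth.csv", index=False)

    meta = {"design": cohort.design, "seed": cohort.seed, "n": len(cohort.patients)}
    meta.update({k: v for k, v in cohort.metadata.items()})
    write_json(meta, directory / "metadata.json")


def read_cohort(directory) -> Cohort:
    """Reconstruct a cohort from its CSV export (trajectories not rebuilt)."""
    directory = Path(directory)
    assess = pd.read_csv(directory / "assessments.csv")
    base = pd.read_csv(directory / "baseline.csv").set_index("patient_id", drop=False)
    truth = pd.read_csv(directory / "truth.csv").set_index("patient_id", drop=False)
    _require_columns(assess, _ASSESSMENT_COLS, "assessments.csv")
    _require_columns(base.reset_index(drop=True), _BASELINE_COLS, "baseline.csv")
    _require_columns(truth.reset_index(drop=True), _TRUTH_COLS, "truth.csv")
    if (assess["time_weeks"] < 0).any():
        raise DomainError("assessments.csv: negative assessment time")
    meta_path = directory / "metadata.json"
    meta = read_json(meta_path) if meta_path.exists() else {}

    patients = []
    for pid, grp in assess.groupby("patient_id", sort=True):
        times = grp["time_weeks"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise DomainError(f"assessments.csv: non-monotone times for patient {pid}")
        scores = grp["symptom_score"].to_numpy(float)
        trow = truth.loc[pid]
        brow = base.loc[pid]
        params = NerdParameters(
            **{name: float(trow[name]) for name in COEFFICIENT_NAMES},
            G0=float(trow["G0"]), N0=float(trow["N0"]),
        )

        def _signal(prefix):
            kind = str(trow[f"{prefix}_kind"])
            tau = trow[f"{prefix}_tau"]
            return InjurySignal(kind=kind, magnitude=float(trow[f"{prefix}_magnitude"]),
                                tau=None if pd.isna(tau) else float(tau))

        arm = grp["arm"].iloc[0]
        arm = None if (pd.isna(arm) or arm == "") else str(arm)
        pscore = persistence_score(times, scores)
        patients.append(PatientRecord(
            id=int(pid), params=params, I=_signal("I"), CI=_signal("CI"),
            severity=str(trow["severity"]),
            biomarkers=Biomarkers(
                vor_asym_pct=float(brow["vor_asym_pct"]),
                sot_composite=float(brow["sot_composite"]),
                primitive_reflex_count=int(brow["primitive_reflex_count"]),
            ),
            schedule=times, scores=scores, trajectory=None,
            persistent_at_3mo=bool(int(brow["persistent_3mo"])),
            persistence_score=pscore,
            recovery_phenotype=str(brow["phenotype"]),
            arm=arm,
        ))
    return Cohort(patients=patients, design=str(meta.get("design", "unknown")),
                  seed=meta.get("seed"), metadata=meta)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_manifest(config: dict, seed, output_files) -> dict:
    """Reproducibility manifest: config, seed, package version, output hashes."""
    from . import __version__

    return {
        "config": config,
        "seed": seed,
        "version": __version__,
        "outputs": {str(f): _sha256(Path(f)) for f in output_files},
    }
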