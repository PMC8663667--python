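"""End-to-end orchestration: generate/load -> score -> merge -> analyze.

One :func:`run_pipeline` call produces, under an output directory, the
scored summaries (glycemic, secure messaging, DSMQ), the merged one-row-
per-patient analysis table, the descriptive comparison table, the
moderated-mediation report, an exclusion ledger naming every patient
dropped on the way to the analysis table, and a manifest (seed, package
version, SHA-256 of every artifact) sufficient to reproduce the run
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import cohort_stats, dsmq as dsmq_mod, glycemic, io, mediation, sm_metrics
from .errors import ValidationError
from .synthetic import SMMonthsDist, SyntheticConfig, generate_cohort


@dataclass
class RunConfig:
    """Inputs, analysis years and model settings for one pipeline run."""

    # either the four CSV paths ...
    patients_csv: str | None = None
    hba1c_csv: str | None = None
    messages_csv: str | None = None
    dsmq_csv: str | None = None
    # ... or a synthesis block
    synthesis: SyntheticConfig | None = None
    exposure_year: int = 2017
    outcome_year: int = 2018
    sensitivity_same_year: bool = False
    tic_span: str = "covered"
    model: mediation.ModelSpec = field(default_factory=mediation.ModelSpec)
    seed: int = 0

    def __post_init__(self):
        if not self.sensitivity_same_year and self.exposure_year >= self.outcome_year:
            raise ValidationError(
                "exposure_year must strictly precede outcome_year "
                "unless sensitivity_same_year is set"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthesis", None)
        model = raw.pop("model", None)
        kwargs = dict(raw)
        if synth is not None:
            dist = synth.pop("sm_months_dist", None)
            if dist is not None:
                synth["sm_months_dist"] = SMMonthsDist(**dist)
            kwargs["synthesis"] = SyntheticConfig(**synth)
        if model is not None:
            for key in ("covariate_names", "w_coding", "w_labels"):
                if key in model:
                    model[key] = tuple(model[key])
            kwargs["model"] = mediation.ModelSpec(**model)
        return cls(**kwargs)


def load_inputs(config: RunConfig):
    """The four input tables, synthesized or read from disk."""
    if config.synthesis is not None:
        # all randomness flows from the run's global seed
        cohort = generate_cohort(dataclasses.replace(config.synthesis, seed=config.seed))
        return cohort.patients, cohort.labs, cohort.messages, cohort.dsmq, cohort.truth
    paths = dict(
        patients=config.patients_csv,
        hba1c=config.hba1c_csv,
        messages=config.messages_csv,
        dsmq=config.dsmq_csv,
    )
    missing = [k for k, v in paths.items() if v is None or not Path(v).exists()]
    if missing:
        raise ValidationError(f"inputs: missing input file(s) for stage(s) {missing}")
    return (
        io.read_patients(paths["patients"]),
        io.read_hba1c(paths["hba1c"]),
        io.read_messages(paths["messages"]),
        io.read_dsmq(paths["dsmq"]),
        None,
    )


def build_analysis_table(
    patients: pd.DataFrame,
    glyc: pd.DataFrame,
    sm: pd.DataFrame,
    scores: pd.DataFrame,
    spec: mediation.ModelSpec,
):
    """Merge the scored summaries into one row per patient, logging exclusions.

    Returns ``(table, exclusions)`` where exclusions is a DataFrame of
    (patient_id, reason) for every patient absent from the final
    complete-case table.
    """
    exclusions = []

    def note(ids, reason):
        exclusions.extend(dict(patient_id=p, reason=reason) for p in ids)

    base = patients[["patient_id", "rurality_code", "age", "income_band", "visits"]].copy()
    df = base.merge(
        glyc[["patient_id", "a1c_tic_percent"]], on="patient_id", how="left"
    )
    note(df.loc[df["a1c_tic_percent"].isna(), "patient_id"], "no in-year HbA1c measurement")
    df = df.merge(
        sm[["patient_id", "months_with_message"]].rename(
            columns={"months_with_message": spec.x_name}
        ),
        on="patient_id",
        how="left",
    )
    df = df.merge(
        scores[["patient_id", "composite"]].rename(columns={"composite": spec.m_name}),
        on="patient_id",
        how="left",
    )
    note(
        df.loc[df["a1c_tic_percent"].notna() & df[spec.m_name].isna(), "patient_id"],
        "missing DSMQ composite",
    )
    df = df.rename(columns={"a1c_tic_percent": spec.y_name})
    model_cols = [spec.x_name, spec.m_name, spec.y_name, spec.w_name, *spec.covariate_names]
    keep = df.dropna(subset=model_cols)
    ex = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return keep.reset_index(drop=True), ex


def analyze_cohort(
    cohort,
    spec: mediation.ModelSpec,
    exposure_year: int = 2017,
    outcome_year: int = 2018,
    tic_span: str = "covered",
) -> mediation.MediationReport:
    """Score a (synthetic or loaded) cohort and fit the moderated-mediation
    model entirely in memory; the file-writing pipeline wraps the same steps."""
    labs = cohort.labs.copy()
    labs["date"] = pd.to_datetime(labs["date"])
    glyc = glycemic.summarize_all(labs, outcome_year, span=tic_span)
    sm = sm_metrics.summarize_all(cohort.messages, cohort.patients["patient_id"], exposure_year)
    scores = dsmq_mod.score_all(cohort.dsmq)
    merged, _ = build_analysis_table(cohort.patients, glyc, sm, scores, spec)
    return mediation.run_moderated_mediation(merged, spec)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full analysis; returns the manifest dict (also written)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients, labs, messages, dsmq_items, truth = load_inputs(config)

    labs = labs.copy()
    labs["date"] = pd.to_datetime(labs["date"])
    glyc = glycemic.summarize_all(labs, config.outcome_year, span=config.tic_span)
    exposure_year = (
        config.outcome_year if config.sensitivity_same_year else config.exposure_year
    )
    sm = sm_metrics.summarize_all(messages, patients["patient_id"], exposure_year)
    scores = dsmq_mod.score_all(dsmq_items)

    spec = dataclasses.replace(config.model, seed=config.seed)
    merged, exclusions = build_analysis_table(patients, glyc, sm, scores, spec)
    # accounting identity: every patient is either analyzed or logged
    assert len(merged) == len(patients) - exclusions["patient_id"].nunique()

    table2 = cohort_stats.table2_summary(merged)
    report = mediation.run_moderated_mediation(merged, spec)

    artifacts = {
        "glycemic_summary.csv": io.write_csv(glyc, outdir / "glycemic_summary.csv"),
        "sm_summary.csv": io.write_csv(sm, outdir / "sm_summary.csv"),
        "dsmq_scores.csv": io.write_csv(scores, outdir / "dsmq_scores.csv"),
        "merged.csv": io.write_csv(merged, outdir / "merged.csv"),
        "exclusions.csv": io.write_csv(exclusions, outdir / "exclusions.csv"),
        "table2.csv": io.write_csv(table2, outdir / "table2.csv"),
        "mediation_report.json": io.write_json(
            report.to_dict(), outdir / "mediation_report.json"
        ),
    }
    (outdir / "mediation_report.txt").write_text(report.to_text(), encoding="utf-8")
    artifacts["mediation_report.txt"] = outdir / "mediation_report.txt"
    if truth is not None:
        artifacts["truth.json"] = io.write_json(truth, outdir / "truth.json")

    manifest = dict(
        package_version=__version__,
        seed=config.seed,
        exposure_year=exposure_year,
        outcome_year=config.outcome_year,
        sensitivity_same_year=config.sensitivity_same_year,
        n_patients=int(len(patients)),
        n_analyzed=int(len(merged)),
        n_excluded=int(exclusions["patient_id"].nunique()),
        n_boot=spec.n_boot,
        artifact_sha256={name: _sha256(Path(p)) for name, p in artifacts.items()},
    )
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
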