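"""End-to-end study analysis: per-profile NCA, pairing, and report tables.

``analyze_study`` runs NCA on every profile, pairs each subject's bead and
IV phases within a cycle to estimate bioavailability from dose-normalised
AUC ratios, and assembles two report tables:

* a *parameter table* (parent drug only) with Dose, terminal k, AUC(0-t),
  nAUC(0-inf), CL (IV) or CL/F (bead), and — for bead phases — F, each
  summarised as mean / SD / CV% / n across subjects;
* a *key-PK table* for both analytes with AUC(0-t), T1/2, Cmax and Tmax.

Bioavailability is reported under both conventions: the mean of per-subject
ratios (the convention the source tables follow) and the ratio of group
mean nAUCs; the two differ whenever exposures vary between animals, so both
are printed with a provenance label.

Profiles for which a parameter cannot be derived ("where possible"
semantics) are excluded from that parameter's summary and listed with
reasons; an unpairable subject is a warning plus exclusion, never a
failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

import numpy as np

from .nca import (
    DEFAULT_REFERENCE_DOSE_MG,
    BioavailabilityResult,
    LambdaZPolicy,
    NCAResult,
    bioavailability,
    run_nca,
    summarize,
)
from .profiles import Analyte, ConcentrationProfile, DoseRecord, Phase, Route

__all__ = ["RunConfig", "StudyReport", "analyze_study", "write_report", "plot_study"]

logger = logging.getLogger("beadpk")

_PHASE_ORDER = (
    Phase.PRIMARY_EMBOLIZATION,
    Phase.SECONDARY_EMBOLIZATION,
    Phase.PRIMARY_IV,
    Phase.SECONDARY_IV,
)
_PHASE_LABEL = {
    Phase.PRIMARY_EMBOLIZATION: "1 Embolization",
    Phase.SECONDARY_EMBOLIZATION: "2 Embolization",
    Phase.PRIMARY_IV: "1 IV",
    Phase.SECONDARY_IV: "2 IV",
}


class RunConfig(BaseModel):
    """Analysis run configuration."""

    reference_dose_mg: float = DEFAULT_REFERENCE_DOSE_MG
    lambda_z_policy: LambdaZPolicy = LambdaZPolicy()
    #: AUC(0-inf) is withheld when the extrapolated tail exceeds this
    #: fraction of the total (non-conforming terminal phase)
    max_extrapolated_fraction: float = 0.50
    #: informational: the assay LLOQs the data were censored at, per analyte
    lloq_parent_ng_ml: float | None = None
    lloq_metabolite_ng_ml: float | None = None
    #: round report tables to the conventional decimals (AUC 2, k 3,
    #: T1/2 / Cmax / Tmax 1); per-profile results always keep full precision
    round_reports: bool = True

    model_config = {"arbitrary_types_allowed": True}


@dataclass
class StudyReport:
    """All analysis outputs of one study."""

    nca_results: list[NCAResult]
    per_profile: pd.DataFrame
    bioavailability: list[BioavailabilityResult]
    parameter_table: pd.DataFrame
    key_pk_table: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)


def _nca_frame(results: list[NCAResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "subject": r.subject_id,
                "phase": r.phase,
                "route": r.route,
                "analyte": r.analyte,
                "dose_mg": r.dose_mg,
                "auc_0_t_ng_h_ml": r.auc_0_t_ng_h_ml,
                "auc_0_inf_ng_h_ml": r.auc_0_inf_ng_h_ml,
                "n_auc_0_inf_ng_h_ml": r.n_auc_0_inf_ng_h_ml,
                "extrapolated_fraction": r.extrapolated_fraction,
                "k_per_h": r.terminal.k_per_h if r.terminal else None,
                "r_squared": r.terminal.r_squared if r.terminal else None,
                "n_points_terminal": r.terminal.n_points if r.terminal else None,
                "t_half_h": r.t_half_h,
                "c_max_ng_ml": r.c_max_ng_ml,
                "t_max_min": r.t_max_min,
                "clearance_ml_min": r.clearance_ml_min,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def _round(value: float, decimals: int, config: RunConfig) -> float:
    return round(value, decimals) if config.round_reports else value


def _summary_rows(label_phase, parameter, values, unit, decimals, config):
    """One mean/SD/CV/n row, or None when no values are available."""
    values = [v for v in values if v is not None]
    if not values:
        return None
    stat = summarize(values)
    return {
        "phase": label_phase,
        "parameter": parameter,
        "mean": _round(stat.mean, decimals, config),
        "sd": _round(stat.sd, decimals, config),
        "cv_percent": _round(stat.cv_percent, 2, config),
        "n": stat.n,
        "units": unit,
    }


def analyze_study(
    profiles: list[ConcentrationProfile],
    dose_records: list[DoseRecord] | None = None,
    run_config: RunConfig | None = None,
) -> StudyReport:
    """Analyse a complete study; see module docstring for the outputs."""
    config = run_config or RunConfig()
    dose_by_key = {
        (d.subject_id, d.phase): d for d in (dose_records or [])
    }

    results: list[NCAResult] = []
    exclusions: list[dict] = []
    for profile in sorted(
        profiles, key=lambda p: (p.subject_id, _PHASE_ORDER.index(p.phase), p.analyte.value)
    ):
        record = dose_by_key.get((profile.subject_id, profile.phase))
        result = run_nca(profile, record, config)
        results.append(result)
        for flag in result.flags:
            exclusions.append(
                {
                    "subject": profile.subject_id,
                    "phase": profile.phase.value,
                    "analyte": profile.analyte.value,
                    "reason": flag,
                }
            )

    by_key = {(r.subject_id, r.phase, r.analyte): r for r in results}
    subjects = sorted({r.subject_id for r in results})

    # --- bioavailability: per subject, per cycle, parent analyte ---------
    f_results: list[BioavailabilityResult] = []
    cycle_nauc: dict[str, dict[str, list[float]]] = {
        "primary": {"bead": [], "iv": []},
        "secondary": {"bead": [], "iv": []},
    }
    for subject in subjects:
        for cycle, bead_phase, iv_phase in (
            ("primary", Phase.PRIMARY_EMBOLIZATION.value, Phase.PRIMARY_IV.value),
            ("secondary", Phase.SECONDARY_EMBOLIZATION.value, Phase.SECONDARY_IV.value),
        ):
            bead = by_key.get((subject, bead_phase, Analyte.PARENT.value))
            iv = by_key.get((subject, iv_phase, Analyte.PARENT.value))
            if bead is None or iv is None:
                logger.warning(
                    "subject %s lacks a %s bead/IV phase pair; excluded from F",
                    subject,
                    cycle,
                )
                exclusions.append(
                    {"subject": subject, "phase": cycle, "analyte": "parent",
                     "reason": "unpaired_phase"}
                )
                continue
            if bead.n_auc_0_inf_ng_h_ml is None or iv.n_auc_0_inf_ng_h_ml is None:
                exclusions.append(
                    {"subject": subject, "phase": cycle, "analyte": "parent",
                     "reason": "nauc_unavailable_for_f"}
                )
                continue
            f_results.append(
                BioavailabilityResult(
                    subject_id=subject,
                    cycle=cycle,
                    f_percent=bioavailability(
                        bead.n_auc_0_inf_ng_h_ml, iv.n_auc_0_inf_ng_h_ml
                    ),
                )
            )
            cycle_nauc[cycle]["bead"].append(bead.n_auc_0_inf_ng_h_ml)
            cycle_nauc[cycle]["iv"].append(iv.n_auc_0_inf_ng_h_ml)

    # --- parameter table (parent) ----------------------------------------
    param_rows = []
    for phase in _PHASE_ORDER:
        label = _PHASE_LABEL[phase]
        sel = [
            by_key[(s, phase.value, Analyte.PARENT.value)]
            for s in subjects
            if (s, phase.value, Analyte.PARENT.value) in by_key
        ]
        cl_name = "CL" if phase.route is Route.IV else "CL/F"
        for parameter, getter, unit, decimals in (
            ("Dose", lambda r: r.dose_mg, "mg", 2),
            ("k", lambda r: r.terminal.k_per_h
             if r.terminal is not None and r.terminal.accepted else None, "/h", 3),
            ("AUC_0-t", lambda r: r.auc_0_t_ng_h_ml, "ng h/ml", 2),
            ("nAUC_0-inf", lambda r: r.n_auc_0_inf_ng_h_ml, "ng h/ml", 2),
            (cl_name, lambda r: r.clearance_ml_min, "ml/min", 2),
        ):
            row = _summary_rows(label, parameter, [getter(r) for r in sel], unit, decimals, config)
            if row is not None:
                param_rows.append(row)
        if phase.route is Route.BEAD:
            cycle = phase.cycle
            f_vals = [f.f_percent for f in f_results if f.cycle == cycle]
            row = _summary_rows(
                label, "F (mean of ratios, as published)", f_vals, "%", 2, config
            )
            if row is not None:
                param_rows.append(row)
            bead_naucs = cycle_nauc[cycle]["bead"]
            iv_naucs = cycle_nauc[cycle]["iv"]
            if bead_naucs and iv_naucs:
                ratio_of_means = bioavailability(
                    float(np.mean(bead_naucs)), float(np.mean(iv_naucs))
                )
                param_rows.append(
                    {
                        "phase": label,
                        "parameter": "F (ratio of means)",
                        "mean": _round(ratio_of_means, 2, config),
                        "sd": float("nan"),
                        "cv_percent": float("nan"),
                        "n": len(bead_naucs),
                        "units": "%",
                    }
                )
    parameter_table = pd.DataFrame(param_rows)

    # --- key PK table (both analytes) -------------------------------------
    key_rows = []
    for analyte in (Analyte.PARENT, Analyte.METABOLITE):
        for phase in _PHASE_ORDER:
            sel = [
                by_key[(s, phase.value, analyte.value)]
                for s in subjects
                if (s, phase.value, analyte.value) in by_key
            ]
            if not sel:
                continue
            label = _PHASE_LABEL[phase]
            for parameter, getter, unit, decimals in (
                ("AUC_0-t", lambda r: r.auc_0_t_ng_h_ml, "ng h/ml", 2),
                ("T_half", lambda r: r.t_half_h, "h", 1),
                ("C_max", lambda r: r.c_max_ng_ml, "ng/ml", 1),
                ("T_max", lambda r: r.t_max_min, "min", 1),
            ):
                row = _summary_rows(
                    label, parameter, [getter(r) for r in sel], unit, decimals, config
                )
                if row is not None:
                    row["analyte"] = analyte.value
                    key_rows.append(row)
    key_pk_table = pd.DataFrame(key_rows)
    if not key_pk_table.empty:
        key_pk_table = key_pk_table[
            ["analyte", "phase", "parameter", "mean", "sd", "cv_percent", "n", "units"]
        ]

    return StudyReport(
        nca_results=results,
        per_profile=_nca_frame(results),
        bioavailability=f_results,
        parameter_table=parameter_table,
        key_pk_table=key_pk_table,
        exclusions=exclusions,
    )


def write_report(report: StudyReport, outdir) -> dict[str, Path]:
    """Write the report as CSV files; regeneration is byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nca_results": outdir / "nca_results.csv",
        "parameter_summary": outdir / "parameter_summary.csv",
        "key_pk_summary": outdir / "key_pk_summary.csv",
        "bioavailability": outdir / "bioavailability.csv",
        "exclusions": outdir / "exclusions.csv",
    }
    report.per_profile.to_csv(paths["nca_results"], index=False)
    report.parameter_table.to_csv(paths["parameter_summary"], index=False)
    report.key_pk_table.to_csv(paths["key_pk_summary"], index=False)
    pd.DataFrame(
        [
            {"subject": f.subject_id, "cycle": f.cycle, "f_percent": f.f_percent}
            for f in report.bioavailability
        ]
    ).to_csv(paths["bioavailability"], index=False)
    pd.DataFrame(report.exclusions).to_csv(paths["exclusions"], index=False)
    return paths


def plot_study(profiles: list[ConcentrationProfile], path) -> None:
    """Concentration-time overview: linear time, log concentration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)
    for ax, analyte in zip(axes, (Analyte.PARENT, Analyte.METABOLITE)):
        for profile in profiles:
            if profile.analyte is not analyte:
                continue
            pts = profile.quantifiable_points()
            if not pts:
                continue
            style = "-o" if profile.route is Route.BEAD else "--s"
            ax.plot(
                [p.time_h for p in pts],
                [p.conc_ng_ml for p in pts],
                style,
                ms=2.5,
                lw=0.8,
                alpha=0.55,
                color="tab:red" if profile.route is Route.BEAD else "tab:blue",
            )
        ax.set_yscale("log")
        ax.set_xlabel("time since end of administration (h)")
        ax.set_title(analyte.value)
    axes[0].set_ylabel("plasma concentration (ng/ml)")
    fig.suptitle("bead (red, solid) vs IV (blue, dashed)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
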