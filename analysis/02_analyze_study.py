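"""Non-compartmental analysis of the simulated study.

Reads results/study/profiles.csv (run 01_simulate_study.py first), runs the
full NCA pipeline, and writes the per-profile results plus the two
group-summary tables (PK parameters with dose-normalised AUC, clearance and
bioavailability; key PK for both analytes) under results/report/.
"""

from pathlib import Path

from beadpk.pipeline import RunConfig, analyze_study, plot_study, write_report
from beadpk.profiles import read_dose_records, read_profiles

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    profiles = read_profiles(ROOT / "study" / "profiles.csv")
    records = read_dose_records(ROOT / "study" / "doses.csv")
    report = analyze_study(profiles, records, RunConfig())
    paths = write_report(report, ROOT / "report")
    plot_study(profiles, ROOT / "report" / "profiles.png")

    f = [b.f_percent for b in report.bioavailability]
    print(f"analysed {len(profiles)} profiles; "
          f"{len(report.exclusions)} parameter exclusions (see exclusions.csv)")
    if f:
        print(f"bioavailability (bead vs IV, mean of {len(f)} subject-cycle "
              f"ratios): {sum(f) / len(f):.1f}%")
    print(report.parameter_table.to_string(index=False))
    for name, path in paths.items():
        print(f"wrote {name}: {path}")


if __name__ == "__main__":
    main()
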