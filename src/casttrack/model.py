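"""Model/Results interface over the measurement pipeline.

`TreatmentEfficacyModel` is built from data (patient scan triplets plus the
cohort manifest); `fit()` runs reference-teeth superimposition, per-tooth
registration and 6-DOF decomposition for every listed movement and returns a
`TreatmentEfficacyResults` carrying the efficacy records, subgroup summaries,
paired tests, and a printable `summary()` — in the spirit of the
model-then-results idiom of the statistical modelling packages.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, scan_io
from .errors import CastTrackError, ConfigurationError
from .movement import EfficacyRecord, measure_patient
from .registration import ICPParams

__all__ = ["TreatmentEfficacyModel", "TreatmentEfficacyResults"]

log = logging.getLogger("casttrack")


class TreatmentEfficacyModel:
    """Achieved-vs-planned tooth-movement efficacy for a scanned cohort.

    Parameters
    ----------
    triplets : mapping patient_id -> (T1, T2, ClinT2) LabeledScans
        Missing patients are allowed; their movements are skipped at fit time
        (dropout accounting).
    manifest : DataFrame
        One row per designed movement (see scan_io.MANIFEST_COLUMNS).
    icp_params, stats_config : optional algorithm controls.
    """

    def __init__(self, triplets, manifest: pd.DataFrame,
                 icp_params: ICPParams | None = None,
                 stats_config: cohort_stats.StatsConfig | None = None):
        scan_io._validate_manifest(manifest)
        if len(manifest) == 0:
            raise ConfigurationError("manifest lists no movements")
        self.triplets = dict(triplets)
        self.manifest = manifest.reset_index(drop=True)
        self.icp_params = icp_params or ICPParams()
        self.stats_config = stats_config or cohort_stats.StatsConfig()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_directory(cls, directory, **kwargs) -> "TreatmentEfficacyModel":
        """Load a cohort laid out as by ``casttrack simulate``:

        ``manifest.csv`` plus ``scans/<patient>_<timepoint>.ply`` with
        ``scans/<patient>_<timepoint>_labels.csv`` sidecars.  Patients with
        missing or unreadable scans are dropped with a log message.
        """
        directory = Path(directory)
        manifest = scan_io.read_manifest(directory / "manifest.csv")
        triplets = {}
        for pid in manifest["patient_id"].unique():
            scans = []
            try:
                for tp in scan_io.TIMEPOINTS:
                    ply = directory / "scans" / f"{pid}_{tp}.ply"
                    labels = directory / "scans" / f"{pid}_{tp}_labels.csv"
                    scans.append(scan_io.read_scan(ply, labels,
                                                   patient_id=str(pid), timepoint=tp))
            except (FileNotFoundError, CastTrackError) as exc:
                log.warning("skipping patient %s: %s", pid, exc)
                continue
            triplets[str(pid)] = tuple(scans)
        return cls(triplets, manifest, **kwargs)

    @classmethod
    def from_simulation(cls, configs=None, seed: int = 0,
                        n_per_subgroup: int = 10, **kwargs):
        """Simulate a cohort (default: the six study subgroups) and wrap it."""
        from .synthetic import generate_cohort, study_configs

        configs = configs or study_configs(seed=seed, n_per_subgroup=n_per_subgroup)
        triplets, truths, manifest = generate_cohort(configs)
        model = cls(triplets, manifest, **kwargs)
        model.ground_truths = truths
        return model

    # -- estimation ---------------------------------------------------------

    def fit(self) -> "TreatmentEfficacyResults":
        """Measure every movement in the manifest; skip missing patients."""
        moved_by_patient: dict[str, list[int]] = {}
        for _, row in self.manifest.iterrows():
            moved_by_patient.setdefault(str(row["patient_id"]), []).append(
                int(row["moved_tooth"]))
        records, skipped = [], []
        for _, row in self.manifest.iterrows():
            pid = str(row["patient_id"])
            if pid not in self.triplets:
                skipped.append((pid, int(row["moved_tooth"]), "scans missing"))
                log.info("skipping %s tooth %s: scans missing", pid, row["moved_tooth"])
                continue
            t1, t2, clin = self.triplets[pid]
            try:
                records.append(measure_patient(
                    t1, t2, clin, row, moved_ids=moved_by_patient[pid],
                    params=self.icp_params))
            except CastTrackError as exc:
                skipped.append((pid, int(row["moved_tooth"]), str(exc)))
                log.warning("skipping %s tooth %s: %s", pid, row["moved_tooth"], exc)
        if not records:
            raise CastTrackError("no analyzable movements in the cohort")
        return TreatmentEfficacyResults(self, records, skipped)


class TreatmentEfficacyResults:
    """Estimates and diagnostics from a fitted cohort."""

    def __init__(self, model: TreatmentEfficacyModel,
                 records: list[EfficacyRecord], skipped):
        self.model = model
        self.records = list(records)
        self.skipped = list(skipped)

    # -- views --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.records],
                            columns=scan_io.RESULT_COLUMNS)

    def subgroup_summaries(self) -> list[cohort_stats.SummaryRow]:
        keys = sorted({(r.group, r.subgroup) for r in self.records})
        return [cohort_stats.summarize_group(
                    [r for r in self.records if (r.group, r.subgroup) == key],
                    cohort_stats.subgroup_label(*key))
                for key in keys]

    def overall_efficacy(self) -> float:
        return cohort_stats.overall_efficacy(self.subgroup_summaries())

    def group_records(self, group: str) -> list[EfficacyRecord]:
        return [r for r in self.records if r.group == group]

    def derotation_splits(self):
        return cohort_stats.split_tables(self.group_records("derotation"),
                                         self.model.stats_config)

    def accounting(self) -> cohort_stats.CohortAccounting:
        n_patients = self.model.manifest["patient_id"].nunique()
        analyzed_pids = {r.patient_id for r in self.records}
        n_drop = n_patients - len(analyzed_pids)
        per_group_designed = self.model.manifest.groupby("group").size()
        frame = self.to_frame()
        per_group_analyzed = frame.groupby("group").size() if len(frame) else []
        return cohort_stats.accounting(n_patients, n_drop,
                                       per_group_designed, per_group_analyzed)

    def report(self) -> dict:
        return cohort_stats.report(self.records, self.model.stats_config)

    def summary(self) -> str:
        """Human-readable cohort report (accuracy table, overall, splits)."""
        rep = self.report()
        acc = self.accounting()
        head = (f"Treatment-efficacy cohort: {acc.n_patients} patients, "
                f"{acc.designed_total} designed movements, "
                f"{acc.analyzed_total} analyzed "
                f"({acc.dropout_percent:.1f}% patient dropout)\n\n")
        return head + rep["text"]

    # -- output -------------------------------------------------------------

    def save(self, directory) -> None:
        """Write results CSV, accuracy/split tables and the text report."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scan_io.write_results(self.records, directory / "results.csv")
        rep = self.report()
        rep["accuracy"].to_csv(directory / "accuracy.csv", index=False)
        rep["by_amount"].to_csv(directory / "derotation_by_amount.csv", index=False)
        rep["by_staging"].to_csv(directory / "derotation_by_staging.csv", index=False)
        (directory / "report.txt").write_text(self.summary())

    def plot_efficacy(self, ax=None):
        """Box-whisker plot of efficacy per subgroup (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        keys = sorted({(r.group, r.subgroup) for r in self.records})
        data = [[r.efficacy_percent for r in self.records
                 if (r.group, r.subgroup) == key] for key in keys]
        ax.boxplot(data, tick_labels=[cohort_stats.subgroup_label(*k) for k in keys])
        ax.set_ylabel("treatment efficacy (%)")
        ax.axhline(100.0, color="grey", lw=0.8, ls="--")
        ax.tick_params(axis="x", rotation=30)
        for lbl in ax.get_xticklabels():
            lbl.set_horizontalalignment("right")
        return ax
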