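"""Cohort-level statistics of treatment efficacy.

Per-subgroup summaries (mean/highest/lowest accuracy, SD, paired-t p-value),
the overall efficacy across subgroups, normality checking, and the derotation
splits by planned amount and by staging.

Unit convention, stated prominently because it is easy to trip over: mean,
highest and lowest accuracy are percentages, while the standard deviation is
reported as a dimensionless fraction of the efficacy ratio (sd = 0.2 means 20
percentage points).  This mirrors how such cohort tables are conventionally
printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .errors import ConfigurationError, DegeneracyError
from .movement import EfficacyRecord

__all__ = [
    "SummaryRow",
    "StatsConfig",
    "CohortAccounting",
    "summarize_group",
    "overall_efficacy",
    "shapiro_wilk",
    "paired_t",
    "split_tables",
    "accounting",
    "report",
]


@dataclass(frozen=True)
class SummaryRow:
    """One row of an accuracy table (a subgroup or a split bin)."""

    label: str
    n: int
    mean_accuracy: float  # percent
    highest: float  # percent
    lowest: float  # percent
    sd: float  # fraction of the efficacy ratio; NaN when n < 2
    p_value: float  # paired t of achieved vs predicted; NaN when untestable

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StatsConfig:
    """Significance level and split thresholds."""

    alpha: float = 0.05
    amount_threshold_deg: float = 15.0
    staging_threshold_deg_per_aligner: float = 1.5

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class CohortAccounting:
    """Designed vs analyzed movement counts and patient dropout."""

    n_patients: int
    n_dropouts: int
    designed_total: int
    analyzed_total: int

    @property
    def dropout_percent(self) -> float:
        return 100.0 * self.n_dropouts / self.n_patients


def summarize_group(records, label: str = "") -> SummaryRow:
    """Mean / highest / lowest accuracy, sample SD and paired-t p for records.

    SD is the (n-1)-denominator sample SD of the efficacy expressed as a
    fraction; undefined (NaN) for a single record.  The p-value is the
    two-sided paired t-test of achieved vs predicted primary components, NaN
    when n < 2 or the differences have zero variance.
    """
    records = list(records)
    if not records:
        raise ConfigurationError("cannot summarize an empty group")
    eff = np.array([r.efficacy_percent for r in records], dtype=float)
    n = len(eff)
    sd = float(np.std(eff / 100.0, ddof=1)) if n >= 2 else math.nan
    p = math.nan
    if n >= 2:
        ach = np.array([r.achieved for r in records], dtype=float)
        pred = np.array([r.predicted for r in records], dtype=float)
        if np.std(ach - pred, ddof=1) > 0:
            _, p = paired_t(ach, pred)
    return SummaryRow(label=label, n=n,
                      mean_accuracy=float(eff.mean()),
                      highest=float(eff.max()), lowest=float(eff.min()),
                      sd=sd, p_value=float(p))


def overall_efficacy(subgroup_rows) -> float:
    """Overall efficacy: the unweighted mean of subgroup mean accuracies (%).

    Each subgroup condition contributes equally regardless of how many of its
    movements survived to analysis.
    """
    rows = list(subgroup_rows)
    if not rows:
        raise ConfigurationError("no subgroup rows to average")
    return float(np.mean([r.mean_accuracy for r in rows]))


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p).  Requires 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ConfigurationError("Shapiro-Wilk needs a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegeneracyError("constant sample: W undefined (zero variance)")
    res = _scistats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def paired_t(achieved, predicted) -> tuple[float, float]:
    """Two-sided paired t-test on (achieved − predicted).

    t < 0 when the achieved movement falls short of the plan on average.
    """
    a = np.asarray(achieved, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ConfigurationError("achieved and predicted must be equal-length vectors")
    if len(a) < 2:
        raise ConfigurationError("paired t-test needs n >= 2")
    d = a - p
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise DegeneracyError("differences have zero variance; t undefined")
    res = _scistats.ttest_rel(a, p)
    return float(res.statistic), float(res.pvalue)


def _empty_row(label: str) -> SummaryRow:
    return SummaryRow(label=label, n=0, mean_accuracy=math.nan,
                      highest=math.nan, lowest=math.nan,
                      sd=math.nan, p_value=math.nan)


def split_tables(records, config: StatsConfig | None = None):
    """Derotation accuracy split by planned amount and by staging.

    Partitions records at the amount threshold (default 15°; boundary values
    go to the lower bin) and at the staging threshold (default 1.5°/aligner),
    each side summarized.  Empty bins yield n = 0 rows with missing stats.
    Returns (by_amount, by_staging) as pairs of SummaryRows (low, high).
    """
    config = config or StatsConfig()
    records = list(records)
    wrong = {r.group for r in records} - {"derotation"}
    if wrong:
        raise ConfigurationError(
            f"amount/staging splits are defined for derotation records, got {sorted(wrong)}")
    at = config.amount_threshold_deg
    st = config.staging_threshold_deg_per_aligner

    def _bin(items, label):
        return summarize_group(items, label) if items else _empty_row(label)

    lo_amt = [r for r in records if r.planned_total <= at]
    hi_amt = [r for r in records if r.planned_total > at]
    lo_stg = [r for r in records if r.staging_per_aligner <= st]
    hi_stg = [r for r in records if r.staging_per_aligner > st]
    by_amount = (_bin(lo_amt, f"derotation <= {at:g} deg"),
                 _bin(hi_amt, f"derotation > {at:g} deg"))
    by_staging = (_bin(lo_stg, f"staging <= {st:g} deg/aligner"),
                  _bin(hi_stg, f"staging > {st:g} deg/aligner"))
    return by_amount, by_staging


def accounting(n_patients: int, n_dropouts: int,
               designed_per_group, analyzed_per_group) -> CohortAccounting:
    """Cohort accounting: totals designed and analyzed, dropout percentage."""
    if n_patients < 1 or not (0 <= n_dropouts <= n_patients):
        raise ConfigurationError("need 0 <= n_dropouts <= n_patients, n_patients >= 1")
    designed = int(np.sum(list(designed_per_group)))
    analyzed = int(np.sum(list(analyzed_per_group)))
    if analyzed > designed:
        raise ConfigurationError("cannot analyze more movements than designed")
    return CohortAccounting(n_patients=n_patients, n_dropouts=n_dropouts,
                            designed_total=designed, analyzed_total=analyzed)


# ---------------------------------------------------------------------------
# reporting

_SUBGROUP_LABEL = {
    ("derotation", "attachment"): "Premolar derotation w Att",
    ("derotation", "none"): "Premolar derotation w/o Att",
    ("distalization", "attachment"): "Distalization w Att",
    ("distalization", "none"): "Distalization w/o Att",
    ("torque", "attachment"): "Incisor torque w Att",
    ("torque", "power_ridge"): "Incisor torque w PR",
}


def subgroup_label(group: str, subgroup: str) -> str:
    return _SUBGROUP_LABEL.get((group, subgroup), f"{group} / {subgroup}")


def report(records, config: StatsConfig | None = None) -> dict:
    """Assemble the cohort report: accuracy table, overall efficacy, splits.

    Returns a dict with DataFrames ``accuracy`` (one row per subgroup),
    ``by_amount`` and ``by_staging`` (derotation splits), the scalar
    ``overall_efficacy_percent`` and a preformatted ``text`` block.
    Deterministic in the input records.
    """
    config = config or StatsConfig()
    records = list(records)
    if not records:
        raise ConfigurationError("no records to report on")
    keys = sorted({(r.group, r.subgroup) for r in records})
    rows = [summarize_group([r for r in records if (r.group, r.subgroup) == key],
                            subgroup_label(*key))
            for key in keys]
    overall = overall_efficacy(rows)
    accuracy = pd.DataFrame([r.to_dict() for r in rows])
    dero = [r for r in records if r.group == "derotation"]
    if dero:
        (amt_lo, amt_hi), (stg_lo, stg_hi) = split_tables(dero, config)
        by_amount = pd.DataFrame([amt_lo.to_dict(), amt_hi.to_dict()])
        by_staging = pd.DataFrame([stg_lo.to_dict(), stg_hi.to_dict()])
    else:
        by_amount = pd.DataFrame(columns=[f.name for f in SummaryRow.__dataclass_fields__.values()]
                                 if hasattr(SummaryRow, "__dataclass_fields__") else [])
        by_staging = by_amount.copy()

    lines = ["Accuracy of tooth movements", "=" * 54]
    for r in rows:
        sd = f"{r.sd:.2f}" if not math.isnan(r.sd) else "--"
        pv = f"{r.p_value:.3f}" if not math.isnan(r.p_value) else "--"
        lines.append(f"{r.label:<30s} n={r.n:<3d} mean {r.mean_accuracy:6.1f}% "
                     f"[{r.lowest:6.1f}, {r.highest:6.1f}] sd {sd} p {pv}")
    lines.append(f"{'Overall efficacy':<30s} {overall:10.1f}%")
    if dero:
        lines.append("")
        lines.append("Derotation splits")
        for r in (amt_lo, amt_hi, stg_lo, stg_hi):
            mean = f"{r.mean_accuracy:6.1f}%" if r.n else "   n/a"
            lines.append(f"  {r.label:<32s} n={r.n:<3d} mean {mean}")
    return {
        "accuracy": accuracy,
        "by_amount": by_amount,
        "by_staging": by_staging,
        "overall_efficacy_percent": overall,
        "text": "\n".join(lines) + "\n",
    }
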