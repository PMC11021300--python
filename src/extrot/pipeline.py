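"""Preregistered and exploratory analyses on trial logs.

Order of operations mirrors the preregistered pipeline: timeout coding, then
a single-pass per-participant 4-SD response-time trial exclusion, then
participant-level exclusions (insufficient rotation in the extended
calibration blocks, group-level RT outliers, low internal accuracy), then the
hypothesis tests:

* H1 — bimodality (BC + dip) of the per-participant RT and accuracy
  differences between the final yoked pair of calibration blocks (7 and 8);
* H2 — paired t plus Bayesian HDI-in-ROPE equivalence on the same blocks;
* H3 — bimodality of extended-strategy use in the choice blocks plus a
  one-sample t against 0.5.

All difference scores use the internal - extended sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bimodality import BimodalityReport, bimodality_report, UndefinedStatisticError
from .engine import TrialRecord, DEADLINE_MS
from .equivalence import EquivalenceReport, RopeSpec, equivalence_report, paired_t

__all__ = [
    "CleanReport",
    "ParticipantSummary",
    "H3Report",
    "RegressionResult",
    "AnovaResult",
    "clean_trials",
    "apply_exclusions",
    "participant_summaries",
    "run_h1",
    "run_h2",
    "run_h3",
    "regress_use",
    "angle_anova",
    "compare_correlations",
    "perseveration_summary",
]

INTERNAL_BLOCKS = (1, 3, 5, 7, 9)
EXTENDED_BLOCKS = (2, 4, 6, 8)
COMPARISON_BLOCKS = (7, 8)  # final yoked internal/extended pair


@dataclass
class CleanReport:
    """Trial-level cleaning counts and participant exclusions."""

    n_timeouts: int = 0
    n_outlier_trials: int = 0
    excluded: dict = field(default_factory=dict)  # pid -> sorted reason codes

    def to_dict(self) -> dict:
        return {"n_timeouts": self.n_timeouts,
                "n_outlier_trials": self.n_outlier_trials,
                "excluded": {str(k): v for k, v in sorted(self.excluded.items())}}


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-participant quantities feeding every hypothesis test."""

    participant: int
    extended_use: float          # choice blocks, proportion rotated
    delta_rt: float              # mean RT block 7 - block 8, ms
    delta_acc: float             # accuracy block 7 - block 8
    rt_block7: float
    rt_block8: float
    acc_block7: float
    acc_block8: float
    use_by_angle: dict           # angle -> extended use in choice blocks


def _by_participant(records) -> dict:
    out: dict = {}
    for r in records:
        out.setdefault(r.participant, []).append(r)
    return out


def clean_trials(records: Sequence[TrialRecord]):
    """Timeout coding then single-pass per-participant 4-SD RT exclusion.

    Returns ``(kept_records, CleanReport)``. Practice trials are dropped.
    Trials at the deadline are coded incorrect with the deadline RT (and
    retained); the 4-SD criterion uses each participant's mean and SD
    computed once, after timeout coding.
    """
    coded = []
    n_timeouts = 0
    for r in records:
        if r.role == "practice":
            continue
        if r.rt >= DEADLINE_MS or r.timeout:
            r = replace(r, rt=DEADLINE_MS, correct=False, timeout=True)
        if r.timeout:
            n_timeouts += 1
        coded.append(r)
    kept = []
    n_outliers = 0
    for pid, recs in _by_participant(coded).items():
        rts = np.array([r.rt for r in recs])
        mean, sd = rts.mean(), rts.std(ddof=1) if len(recs) > 1 else 0.0
        for r in recs:
            if sd > 0 and abs(r.rt - mean) > 4.0 * sd:
                n_outliers += 1
            else:
                kept.append(r)
    kept.sort(key=lambda r: (r.participant, r.block, r.trial))
    return kept, CleanReport(n_timeouts=n_timeouts, n_outlier_trials=n_outliers)


def apply_exclusions(records: Sequence[TrialRecord],
                     rotation_min: float = 0.85,
                     rt_sd_limit: float = 2.5,
                     accuracy_min: float = 0.80,
                     calibration_acc_gap: Optional[float] = None,
                     calibration_rt_gap: Optional[float] = None) -> CleanReport:
    """Participant-level exclusion flags on cleaned records.

    Reasons: ``low_rotation`` (rotated in < 85% of extended-calibration-block
    trials combined), ``rt_outlier`` (grand-mean RT outside group mean +/-
    2.5 group SD), ``low_accuracy`` (combined accuracy over the internal
    calibration blocks < 80%), and optionally ``calibration_outlier``
    (absolute block-7-vs-8 accuracy or RT gap above a configured threshold;
    disabled by default).
    """
    per = _by_participant(records)
    grand = {pid: np.mean([r.rt for r in recs]) for pid, recs in per.items()}
    gvals = np.array(list(grand.values()))
    gmean = gvals.mean()
    gsd = gvals.std(ddof=1) if len(gvals) > 1 else 0.0
    report = CleanReport()
    for pid, recs in sorted(per.items()):
        reasons = []
        ext = [r for r in recs if r.block in EXTENDED_BLOCKS]
        if ext and np.mean([r.rotated for r in ext]) < rotation_min:
            reasons.append("low_rotation")
        if gsd > 0 and abs(grand[pid] - gmean) > rt_sd_limit * gsd:
            reasons.append("rt_outlier")
        intr = [r.correct for r in recs if r.block in INTERNAL_BLOCKS]
        if intr and np.mean(intr) < accuracy_min:
            reasons.append("low_accuracy")
        if calibration_acc_gap is not None or calibration_rt_gap is not None:
            s = _summary_one(pid, recs)
            if ((calibration_acc_gap is not None
                 and abs(s.delta_acc) > calibration_acc_gap)
                    or (calibration_rt_gap is not None
                        and abs(s.delta_rt) > calibration_rt_gap)):
                reasons.append("calibration_outlier")
        if reasons:
            report.excluded[pid] = reasons
    return report


def _summary_one(pid: int, recs: Sequence[TrialRecord]) -> ParticipantSummary:
    b7 = [r for r in recs if r.block == COMPARISON_BLOCKS[0]]
    b8 = [r for r in recs if r.block == COMPARISON_BLOCKS[1]]
    choice = [r for r in recs if r.role == "choice"]
    if not (b7 and b8 and choice):
        raise ValueError(f"participant {pid}: missing block 7/8 or choice data")
    rt7 = float(np.mean([r.rt for r in b7]))
    rt8 = float(np.mean([r.rt for r in b8]))
    acc7 = float(np.mean([r.correct for r in b7]))
    acc8 = float(np.mean([r.correct for r in b8]))
    use_by_angle = {}
    for angle in sorted({r.angle for r in choice}):
        sub = [r.rotated for r in choice if r.angle == angle]
        use_by_angle[int(angle)] = float(np.mean(sub))
    return ParticipantSummary(
        participant=pid,
        extended_use=float(np.mean([r.rotated for r in choice])),
        delta_rt=rt7 - rt8, delta_acc=acc7 - acc8,
        rt_block7=rt7, rt_block8=rt8, acc_block7=acc7, acc_block8=acc8,
        use_by_angle=use_by_angle)


def participant_summaries(records: Sequence[TrialRecord],
                          exclude: Sequence[int] = ()) -> pd.DataFrame:
    """One row per retained participant; angle-wise use in u60/u120/u180."""
    rows = []
    for pid, recs in sorted(_by_participant(records).items()):
        if pid in set(exclude):
            continue
        s = _summary_one(pid, recs)
        row = {"participant": s.participant, "extended_use": s.extended_use,
               "delta_rt": s.delta_rt, "delta_acc": s.delta_acc,
               "rt_block7": s.rt_block7, "rt_block8": s.rt_block8,
               "acc_block7": s.acc_block7, "acc_block8": s.acc_block8}
        for angle, u in s.use_by_angle.items():
            row[f"u{angle}"] = u
        rows.append(row)
    return pd.DataFrame(rows)


def run_h1(deltas, n_null: int = 2000, rng=None) -> BimodalityReport:
    """Bimodality diagnostic of per-participant difference scores."""
    try:
        return bimodality_report(deltas, n_null=n_null, rng=rng)
    except UndefinedStatisticError as exc:
        raise UndefinedStatisticError(f"H1 delta vector: {exc}") from exc


def run_h2(block7, block8, rope: RopeSpec, rng=None) -> EquivalenceReport:
    """Paired t + HDI + ROPE verdict on block 7 minus block 8 means."""
    return equivalence_report(block7, block8, rope, rng=rng)


@dataclass(frozen=True)
class H3Report:
    """Bimodality of strategy use plus the one-sample test against 0.5."""

    bimodality: BimodalityReport
    t: float
    df: int
    p: float
    mean_use: float
    t_degenerate: bool
    h3_2_applicable: bool  # the mean test is preregistered only if unimodal

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bimodality"] = self.bimodality.to_dict()
        return d


def run_h3(u, n_null: int = 2000, rng=None) -> H3Report:
    """H3-1 bimodality of extended use; H3-2 one-sample t versus mu = 0.5."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("extended use must lie in [0, 1]")
    try:
        bim = bimodality_report(u, n_null=n_null, rng=rng)
    except UndefinedStatisticError as exc:
        raise UndefinedStatisticError(f"H3 use vector: {exc}") from exc
    n = u.size
    if np.ptp(u) == 0.0:
        t = 0.0 if u[0] == 0.5 else float(np.sign(u[0] - 0.5) * np.inf)
        p = 1.0 if u[0] == 0.5 else 0.0
        degenerate = True
    else:
        t, p = stats.ttest_1samp(u, 0.5)
        t, p = float(t), float(p)
        degenerate = False
    return H3Report(bimodality=bim, t=t, df=n - 1, p=p,
                    mean_use=float(u.mean()), t_degenerate=degenerate,
                    h3_2_applicable=bim.verdict != "bimodal")


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    f: float
    p: float
    r2_adj: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def regress_use(u, delta) -> RegressionResult:
    """Simple OLS of extended use on a performance delta (internal - extended)."""
    u = np.asarray(u, dtype=float)
    d = np.asarray(delta, dtype=float)
    if u.shape != d.shape or u.ndim != 1 or u.size < 3:
        raise ValueError("regress_use needs equal-length 1-D samples, n >= 3")
    if np.ptp(d) == 0.0:
        raise ValueError("predictor has zero variance")
    n = u.size
    dc = d - d.mean()
    slope = float(np.dot(dc, u) / np.dot(dc, dc))
    intercept = float(u.mean() - slope * d.mean())
    fitted = intercept + slope * d
    ss_res = float(np.sum((u - fitted) ** 2))
    ss_tot = float(np.sum((u - u.mean()) ** 2))
    if ss_res <= 1e-300 * max(ss_tot, 1.0):
        return RegressionResult(intercept, slope, float(np.inf), 0.0, 1.0, n)
    f = (ss_tot - ss_res) / (ss_res / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(intercept, slope, float(f), p, float(r2_adj), n)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: float          # Greenhouse-Geisser corrected
    df2: float
    p: float            # GG-corrected p
    epsilon: float
    eta2_g: float

    def to_dict(self) -> dict:
        return asdict(self)


def angle_anova(use_table) -> AnovaResult:
    """One-way repeated-measures ANOVA of extended use across angles.

    ``use_table`` is an ``(n, 3)`` array-like or a DataFrame with one column
    per angle; rows are participants. Degrees of freedom carry the
    Greenhouse-Geisser correction; effect size is generalized eta squared.
    """
    import pingouin as pg

    tab = np.asarray(pd.DataFrame(use_table), dtype=float)
    if tab.ndim != 2 or tab.shape[1] < 2 or np.any(~np.isfinite(tab)):
        raise ValueError("angle_anova needs a complete (n, k>=2) table")
    n, k = tab.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "angle": np.tile(np.arange(k), n),
        "use": tab.ravel(),
    })
    aov = pg.rm_anova(data=long, dv="use", within="angle", subject="subject",
                      correction=True, detailed=True, effsize="ng2")
    row = aov.loc[aov["Source"] == "angle"].iloc[0]

    def col(*names):
        for name in names:
            if name in row.index and np.isfinite(row[name]):
                return float(row[name])
        return np.nan
    eps = col("eps")
    if not np.isfinite(eps):
        eps = 1.0  # degenerate case (e.g. zero condition variance)
    p = col("p_GG_corr", "p-GG-corr", "p_unc", "p-unc")
    f = float(row["F"]) if np.isfinite(row["F"]) else 0.0
    if not np.isfinite(p):
        p = 1.0 if f == 0.0 else np.nan
    ng2 = col("ng2")
    return AnovaResult(f=f, df1=eps * (k - 1), df2=eps * (k - 1) * (n - 1),
                       p=p, epsilon=eps, eta2_g=0.0 if not np.isfinite(ng2) else ng2)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple:
    """Fisher-z test of two independent correlations: ``(z, p)``."""
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
        if n <= 3:
            raise ValueError("group sizes must exceed 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def perseveration_summary(u, thresholds=(0.90, 0.95, 1.0),
                          strict: bool = False) -> dict:
    """Fractions of near-exclusive strategy users at each threshold.

    For threshold tau: extended-side perseverators have use >= tau,
    internal-side have use <= 1 - tau (strict comparisons when ``strict``).
    Returns ``{tau: {"internal": p, "extended": p, "total": p}}``.
    """
    u = np.asarray(u, dtype=float)
    if u.size == 0 or np.any((u < 0) | (u > 1)):
        raise ValueError("u must be a non-empty sample in [0, 1]")
    out = {}
    for tau in thresholds:
        if strict:
            ext = np.mean(u > tau)
            intern = np.mean(u < 1.0 - tau)
        else:
            # tolerance absorbs float rounding in 1 - tau (e.g. 1 - 0.9)
            ext = np.mean(u >= tau - 1e-12)
            intern = np.mean(u <= (1.0 - tau) + 1e-12)
        out[tau] = {"internal": float(intern), "extended": float(ext),
                    "total": float(intern + ext)}
    return out
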