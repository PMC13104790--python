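"""Agreement and longitudinal summaries for the anesthesia study design.

Covers the descriptive statistics the imaging pipeline feeds: ordinary
least-squares regression with R^2 (e.g. OCT-derived heart rate against a
blood-pressure monitor), Bland-Altman bias and 1.96-SD limits of agreement,
per-subject slopes over time averaged within sex x anesthetic groups, and
pooled group means.  Inferential mixed-effects modelling is deliberately out
of scope: the tidy long-format records this module consumes and emits are
shaped for off-the-shelf mixed-model software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "linear_fit",
    "bland_altman",
    "per_subject_slopes",
    "group_summary",
    "make_synthetic_cohort",
    "RECORD_COLUMNS",
]

#: tidy long-format schema for longitudinal records
RECORD_COLUMNS = ("subject", "sex", "anesthetic", "minutes", "parameter", "value")

PARAMETER_UNITS = {
    "HR": "bpm",
    "mean_BP": "mm Hg",
    "MAV_ILM": "nm/ms",
    "MAV_ISOS": "nm/ms",
    "RT": "um",
    "RT_minus_SVP": "um",
    "RT_at_SVP": "um",
    "SVP_density": "%",
}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class BlandAltmanResult:
    means: np.ndarray
    diffs: np.ndarray
    bias: float
    loa_lower: float
    loa_upper: float
    n: int


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R^2 = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sstats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept), r2=r2, n=x.size)


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement: per-pair mean and difference, bias, and
    limits of agreement ``bias +/- 1.96 x SD(differences)`` (sample SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-D of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    means = (a + b) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        means=means,
        diffs=diffs,
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=a.size,
    )


def per_subject_slopes(records: pd.DataFrame, parameter: str):
    """OLS slope per subject over minutes; group slope = unweighted mean of
    subject slopes within each sex x anesthetic cell.

    Subjects with fewer than 2 time points are excluded and reported.
    Returns ``(per_subject: DataFrame, group: DataFrame, excluded: list)``.
    """
    df = records[records["parameter"] == parameter]
    rows, excluded = [], []
    for (subj, sex, anes), sub in df.groupby(["subject", "sex", "anesthetic"]):
        if len(sub) < 2 or sub["minutes"].nunique() < 2:
            excluded.append(subj)
            continue
        fit = linear_fit(sub["minutes"].to_numpy(), sub["value"].to_numpy())
        rows.append(
            {"subject": subj, "sex": sex, "anesthetic": anes,
             "slope": fit.slope, "n_points": fit.n}
        )
    per_subject = pd.DataFrame(rows, columns=["subject", "sex", "anesthetic", "slope", "n_points"])
    if per_subject.empty:
        group = pd.DataFrame(columns=["sex", "anesthetic", "group_slope", "n_subjects"])
    else:
        group = (
            per_subject.groupby(["sex", "anesthetic"], as_index=False)
            .agg(group_slope=("slope", "mean"), n_subjects=("slope", "size"))
        )
    return per_subject, group, excluded


def group_summary(records: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Pooled mean +/- sample SD per sex x anesthetic cell.

    All records of all time points and subjects in a cell are pooled.  A
    single-record cell reports SD 0; an empty cell simply does not appear
    (missing, not zero).
    """
    df = records[records["parameter"] == parameter]
    rows = []
    for (sex, anes), sub in df.groupby(["sex", "anesthetic"]):
        vals = sub["value"].to_numpy(dtype=float)
        rows.append(
            {
                "sex": sex,
                "anesthetic": anes,
                "parameter": parameter,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows, columns=["sex", "anesthetic", "parameter", "mean", "sd", "n"])


def make_synthetic_cohort(
    parameter: str = "HR",
    cell_means: dict[tuple[str, str], float] | None = None,
    slope_mu: float = 1.0,
    slope_sd: float = 0.3,
    noise_sd: float = 5.0,
    n_subjects_per_cell: int = 6,
    times_min=(0, 5, 10, 15, 20, 25),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a tidy longitudinal cohort with known per-cell means and a
    known mean per-subject slope, for recovery tests of the summaries.

    Each subject's trajectory is ``cell_mean + slope * t + noise`` with the
    slope drawn N(slope_mu, slope_sd).  Mirrors the study design of repeated
    imaging every 5 minutes under three anesthetics for both sexes.
    """
    rng = np.random.default_rng(seed)
    if cell_means is None:
        cell_means = {
            (sex, anes): base
            for sex, base in (("female", 450.0), ("male", 480.0))
            for anes in ("ISO", "MMFK", "KX")
        }
    rows = []
    sid = 0
    for (sex, anes), mean in cell_means.items():
        for _ in range(n_subjects_per_cell):
            sid += 1
            slope = rng.normal(slope_mu, slope_sd)
            for t in times_min:
                rows.append(
                    {
                        "subject": f"m{sid:03d}",
                        "sex": sex,
                        "anesthetic": anes,
                        "minutes": float(t),
                        "parameter": parameter,
                        "value": mean + slope * t + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
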