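"""Reproducibility and reliability statistics.

Reproducibility of repeated measurements on one case is summarised by
the maximum absolute deviation from the case mean and a z-based 95%
confidence interval of the mean, ``1.96 * s / sqrt(n)`` with ``s`` the
sample standard deviation.  Inter-rater reliability uses the intra-class
correlation coefficient from the two-way ANOVA decomposition; the
default variant is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — the standard choice when raters are
regarded as interchangeable.  Reported values are rounded half away
from zero to one decimal, matching clinical reporting precision.
"""
from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedIccError(ValueError):
    """ICC is undefined (zero total variance)."""


def round_report(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 0.25 -> 0.3, -0.25 -> -0.3)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _values(v) -> np.ndarray:
    a = np.asarray(v, dtype=np.float64).ravel()
    if len(a) < 2:
        raise ValueError(f"need at least 2 values, got {len(a)}")
    if not np.all(np.isfinite(a)):
        raise ValueError("values contain non-finite entries")
    return a


def max_abs_dev(values) -> float:
    """Maximum absolute deviation from the mean."""
    a = _values(values)
    return float(np.max(np.abs(a - a.mean())))


def ci95(values) -> float:
    """z-based 95% half-width of the mean: ``1.96 * s / sqrt(n)``."""
    a = _values(values)
    return float(1.96 * a.std(ddof=1) / np.sqrt(len(a)))


def effective_dose(dlp_mGy_cm: float, coefficient_mSv_per_mGy_cm: float) -> float:
    """Effective dose (mSv) = dose-length-product x anatomic conversion
    coefficient."""
    if dlp_mGy_cm < 0 or coefficient_mSv_per_mGy_cm < 0:
        raise ValueError("dose-length-product and coefficient must be non-negative")
    return float(dlp_mGy_cm * coefficient_mSv_per_mGy_cm)


# ---------------------------------------------------------------------------
# intra-class correlation
# ---------------------------------------------------------------------------

def _anova_mean_squares(m: np.ndarray):
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, ss_total


def icc(matrix, model: str = "ICC(2,1)") -> float:
    """Intra-class correlation from a complete subjects x raters matrix.

    Supported models: ``ICC(2,1)`` (two-way random, absolute agreement,
    single measurement; default), ``ICC(3,1)`` (two-way mixed,
    consistency), and the average-measure forms ``ICC(2,k)``/``ICC(3,k)``.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >=2 subjects and >=2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains missing or non-finite cells")
    n, k = m.shape
    msr, msc, mse, ss_total = _anova_mean_squares(m)
    if ss_total < 1e-30:
        raise UndefinedIccError("zero total variance; ICC undefined")
    if model == "ICC(2,1)":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif model == "ICC(3,1)":
        denom = msr + (k - 1) * mse
    elif model == "ICC(2,k)":
        denom = msr + (msc - mse) / n
        return float((msr - mse) / denom)
    elif model == "ICC(3,k)":
        return float((msr - mse) / msr)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    return float((msr - mse) / denom)


def icc_band(value: float) -> str:
    """Qualitative reliability band for an ICC value.

    > 0.9 excellent; (0.80, 0.9] very good; (0.75, 0.80] good;
    [0.5, 0.75] moderate; < 0.5 poor.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if value > 0.9:
        return "excellent"
    if value > 0.80:
        return "very good"
    if value > 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

@dataclass
class MeasurementTable:
    """Long-format table of repeated measurements.

    Columns: ``case``, ``operator``, ``run``, ``variable``, ``value`` —
    one row per measured quantity per processing run.
    """

    data: pd.DataFrame

    REQUIRED_COLUMNS = ("case", "operator", "run", "variable", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        bad = self.data[~np.isfinite(pd.to_numeric(self.data["value"], errors="coerce"))]
        if len(bad):
            raise ValueError(f"non-numeric value at row(s) {list(bad.index[:5])}")
        self.data = self.data.assign(value=self.data["value"].astype(float))

    @staticmethod
    def from_csv(path) -> "MeasurementTable":
        return MeasurementTable(pd.read_csv(path))

    def repro_summary(self, decimals: int | None = 1) -> pd.DataFrame:
        """Per case x variable: max |deviation from mean|, 95% CI, n.

        ``decimals=None`` returns unrounded values; otherwise values are
        rounded half away from zero for reporting.
        """
        rows = []
        for (case, var), grp in self.data.groupby(["case", "variable"], sort=True):
            v = grp["value"].to_numpy()
            m, c = max_abs_dev(v), ci95(v)
            if decimals is not None:
                m, c = round_report(m, decimals), round_report(c, decimals)
            rows.append({"case": case, "variable": var,
                         "max_abs_dev": m, "ci95": c, "n": len(v)})
        return pd.DataFrame(rows)

    def icc_by_variable(self, model: str = "ICC(2,1)") -> pd.DataFrame:
        """ICC per variable with cases as subjects and (operator, run)
        pairs as raters; requires a complete block per variable."""
        rows = []
        for var, grp in self.data.groupby("variable", sort=True):
            wide = grp.pivot_table(index="case", columns=["operator", "run"],
                                   values="value", aggfunc="first")
            if wide.isna().any().any():
                raise ValueError(f"incomplete case x rater block for variable {var!r}")
            value = icc(wide.to_numpy(), model=model)
            rows.append({"variable": var, "icc": value, "model": model,
                         "band": icc_band(value),
                         "n_subjects": wide.shape[0], "n_raters": wide.shape[1]})
        return pd.DataFrame(rows)


def simulate_rater_study(n_subjects: int = 11, n_raters: int = 2,
                         variables: int = 6, subject_sd: float = 2.5,
                         rater_noise_sd: float = 0.3,
                         seed: int = 42) -> dict[str, np.ndarray]:
    """Simulate an inter-rater study: per variable, each subject has a
    latent value Normal(0, subject_sd^2) and each rater observes it with
    independent Normal(0, rater_noise_sd^2) error.  Returns
    ``{variable_name: subjects x raters matrix}``."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(variables):
        latent = rng.normal(0.0, subject_sd, size=n_subjects)
        noise = rng.normal(0.0, rater_noise_sd, size=(n_subjects, n_raters))
        out[f"var{i + 1}"] = latent[:, None] + noise
    return out
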