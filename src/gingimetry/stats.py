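"""Statistical layer: clustered group comparisons, agreement, planning.

Teeth are clustered within patients, so factor comparisons (recession type,
jaw, tooth type) use a linear mixed model with a patient random intercept by
default; ``patient_effect="fixed"`` instead absorbs patients as fixed dummy
effects in an OLS fit.  All pairwise contrasts are corrected with Scheffe's
method: the contrast F statistic is divided by the factor dimension (k - 1)
and referred to F_{k-1, df}, which guarantees adjusted p >= unadjusted p.

Rater/replicate agreement uses the intraclass correlation coefficient from
the two-way ANOVA mean squares -- ICC(2,1), two-way random effects, absolute
agreement, single measurement -- with an F-based confidence interval;
ICC(3,1) (consistency) is available as an option.

Sample-size planning for a single-arm non-inferiority comparison of mean
root coverage against a reference value uses the normal approximation
n = ceil(((z_{1-alpha/2} + z_{power}) * sd / margin)^2); a variance-inflation
adjusted figure for clustered teeth is reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

FACTORS = ("recession_type", "jaw", "tooth_type")

#: outcome columns a study table may carry
OUTCOMES = (
    "recession_depth_pre",
    "recession_reduction",
    "mrc_percent",
    "thickness_gain",
)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# study table
# ---------------------------------------------------------------------------


def build_study_table(
    records: Sequence, patient_id: str, collapse_replicates: bool = True
) -> pd.DataFrame:
    """Rows of per-tooth outcomes for one patient's case.

    With ``collapse_replicates`` (default) the replicate/rater measurements
    of each tooth are averaged into a single row -- the per-tooth mean is
    what enters the group comparisons.
    """
    from .measurement import records_to_frame

    df = records_to_frame(records)
    df.insert(0, "patient_id", patient_id)
    if collapse_replicates and len(df):
        keys = ["patient_id", "tooth_id", "jaw", "tooth_type", "recession_type"]
        numeric = [
            "recession_depth_pre",
            "recession_depth_post",
            "recession_reduction",
            "mrc_percent",
            "thickness_gain",
        ]
        agg = {c: "mean" for c in numeric}
        agg["complete_coverage"] = "first"
        agg["cej_available"] = "first"
        df = df.groupby(keys, as_index=False).agg(agg)
    return df


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    if "patient_id" not in table or table["patient_id"].isna().any():
        raise StatsError("study table needs non-empty patient_id")
    keys = ["tooth_id"]
    for extra in ("rater_id", "replicate_index"):
        if extra in table:
            keys.append(extra)
    if table.duplicated(subset=["patient_id"] + keys).any():
        raise StatsError("duplicate (patient, tooth, rater, replicate) rows")
    return table


# ---------------------------------------------------------------------------
# clustered group comparison with Scheffe-adjusted contrasts
# ---------------------------------------------------------------------------


@dataclass
class PairwiseContrast:
    level_a: str
    level_b: str
    estimate: float
    se: float
    p_unadjusted: float
    p_scheffe: float


@dataclass
class GroupComparison:
    outcome: str
    factor: str
    levels: list
    means: dict
    sds: dict
    counts: dict
    overall_f: float
    overall_p: float
    df_num: int
    df_den: float
    pairwise: list
    patient_effect: str


def _fit_random_intercept(y, X, groups):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception:
            res = model.fit(reml=True, method="powell")
    k_fe = X.shape[1]
    beta = np.asarray(res.params)[:k_fe]
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    return beta, cov


def group_compare(
    table: pd.DataFrame,
    outcome: str,
    factor: str,
    patient_effect: str = "random",
) -> GroupComparison:
    """Compare an outcome across the levels of a clustering-aware factor.

    Returns per-level raw means +/- SD, an overall Wald F test of the factor
    (denominator df by the containment rule N - k - n_patients + 1), and all
    pairwise contrasts with unadjusted and Scheffe-adjusted p-values.
    """
    if factor not in table.columns:
        raise StatsError(f"factor {factor!r} not in table")
    df = table.dropna(subset=[outcome, factor]).copy()
    levels = sorted(df[factor].astype(str).unique())
    k = len(levels)
    if k < 2:
        raise StatsError(f"factor {factor!r} has a single level")
    if df["patient_id"].nunique() < 2:
        raise StatsError("need >= 2 patients")

    y = df[outcome].to_numpy(dtype=float)
    fac = df[factor].astype(str).to_numpy()
    n = len(y)
    g = df["patient_id"].nunique()

    # cell dummies relative to the first level, plus intercept
    X = np.ones((n, k))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (fac == lev).astype(float)

    if patient_effect == "random":
        beta, cov = _fit_random_intercept(y, X, df["patient_id"].to_numpy())
        df_den = max(n - k - g + 1, 1)
    elif patient_effect == "fixed":
        # absorb patients as fixed dummies (the literal reading)
        patients = sorted(df["patient_id"].unique())
        P = np.zeros((n, len(patients) - 1))
        pat = df["patient_id"].to_numpy()
        for j, p in enumerate(patients[1:]):
            P[:, j] = (pat == p).astype(float)
        Xf = np.hstack([X, P])
        beta_full, res_ss, rank, _ = np.linalg.lstsq(Xf, y, rcond=None)
        resid = y - Xf @ beta_full
        df_den = max(n - np.linalg.matrix_rank(Xf), 1)
        sigma2 = float(resid @ resid) / df_den
        cov_full = sigma2 * np.linalg.pinv(Xf.T @ Xf)
        beta = beta_full[:k]
        cov = cov_full[:k, :k]
    else:
        raise StatsError("patient_effect must be 'random' or 'fixed'")

    # overall Wald F on the k-1 factor coefficients
    b = beta[1:]
    V = cov[1:, 1:]
    try:
        wald = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        wald = float(b @ np.linalg.pinv(V) @ b)
    f_stat = wald / (k - 1)
    overall_p = float(sps.f.sf(f_stat, k - 1, df_den))

    # pairwise contrasts on cell means: level i mean - level j mean
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(k)
            if i > 0:
                c[i] = 1.0
            if j > 0:
                c[j] -= 1.0
            est = float(c @ beta)
            se = float(np.sqrt(max(c @ cov @ c, 0.0)))
            if se == 0.0:
                f_c = 0.0 if est == 0.0 else np.inf
            else:
                f_c = (est / se) ** 2
            p_un = float(sps.f.sf(f_c, 1, df_den))
            p_sch = float(sps.f.sf(f_c / (k - 1), k - 1, df_den))
            pairwise.append(
                PairwiseContrast(levels[i], levels[j], est, se, p_un, min(p_sch, 1.0))
            )

    means = {lev: float(y[fac == lev].mean()) for lev in levels}
    sds = {
        lev: float(y[fac == lev].std(ddof=1)) if (fac == lev).sum() > 1 else 0.0
        for lev in levels
    }
    counts = {lev: int((fac == lev).sum()) for lev in levels}
    return GroupComparison(
        outcome=outcome,
        factor=factor,
        levels=levels,
        means=means,
        sds=sds,
        counts=counts,
        overall_f=float(f_stat),
        overall_p=overall_p,
        df_num=k - 1,
        df_den=float(df_den),
        pairwise=pairwise,
        patient_effect=patient_effect,
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    form: str
    n_rows: int
    n_cols: int
    n_dropped: int
    degenerate: bool = False


def icc(
    ratings: np.ndarray, form: str = "ICC2", alpha: float = 0.05
) -> ICCResult:
    """Intraclass correlation from the two-way mean-squares decomposition.

    ``ratings`` is (targets x raters-or-replicates).  ``form='ICC2'`` is the
    two-way random-effects absolute-agreement single-measurement coefficient;
    ``'ICC3'`` the consistency variant.  Rows with missing cells are dropped
    (count reported).  Zero between-target variance yields 0 with a warning.
    """
    M = np.asarray(ratings, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise StatsError("ratings must be 2-D with >= 2 columns")
    keep = np.isfinite(M).all(axis=1)
    n_dropped = int((~keep).sum())
    M = M[keep]
    n, k = M.shape
    if n < 5:
        raise StatsError("need >= 5 complete rows")

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((M - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom_check = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if msr <= 1e-300 or (msr - mse <= 0 and denom_check <= 1e-300):
        warnings.warn("zero between-target variance: ICC degenerate, returning 0")
        return ICCResult(0.0, np.nan, np.nan, form, n, k, n_dropped, degenerate=True)

    if form == "ICC3":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            lo = hi = est
        else:
            f_obs = msr / mse
            f_l = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            f_u = f_obs * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (f_l - 1) / (f_l + k - 1)
            hi = (f_u - 1) / (f_u + k - 1)
    elif form == "ICC2":
        est = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        if mse == 0:
            lo = hi = est
        else:
            # McGraw & Wong F-based interval with Satterthwaite df
            fj = msc / mse
            a = (k * est) / (n * (1 - est))
            b = 1 + (k * est * (n - 1)) / (n * (1 - est))
            v = (a * fj + b) ** 2 / (
                (a**2 * fj**2) / (k - 1) + b**2 / ((n - 1) * (k - 1))
            )
            f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_u * mse)) / (
                f_u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = (n * (f_l * msr - mse)) / (
                k * msc + (k * n - k - n) * mse + n * f_l * msr
            )
    else:
        raise StatsError("form must be 'ICC2' or 'ICC3'")

    est = float(np.clip(est, -1.0, 1.0))
    return ICCResult(est, float(lo), float(hi), form, n, k, n_dropped)


# ---------------------------------------------------------------------------
# non-inferiority sample size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeSpec:
    """Planning inputs, in percentage points of mean root coverage."""

    reference_mean: float = 87.0
    noninferiority_margin: float = 10.0
    sd: float = 25.0
    power: float = 0.90
    alpha: float = 0.05
    variance_inflation_factor: float = 3.0

    def validate(self) -> "SampleSizeSpec":
        if not 0 < self.power < 1:
            raise StatsError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise StatsError("alpha must be in (0, 1)")
        if self.noninferiority_margin <= 0:
            raise StatsError("margin must be > 0")
        if self.sd < 0:
            raise StatsError("sd must be >= 0")
        if self.variance_inflation_factor < 1:
            raise StatsError("variance inflation factor must be >= 1")
        return self


@dataclass
class SampleSizeResult:
    n_teeth: int           # headline: ceil of the normal-approximation formula
    n_raw: float           # the un-rounded formula value
    n_vif_adjusted: int    # ceil(VIF * raw), for teeth clustered within patients


def noninferiority_sample_size(spec: SampleSizeSpec) -> SampleSizeResult:
    """n = ceil(((z_{1-alpha/2} + z_{power}) * sd / margin)^2).

    The alpha quantile is two-sided.  The VIF-adjusted count multiplies the
    raw value by the variance inflation factor before rounding, the standard
    correction when several teeth per patient contribute.  ``sd = 0``
    degenerates to the enforced minimum of one tooth.
    """
    spec.validate()
    if spec.sd == 0:
        return SampleSizeResult(1, 0.0, 1)
    if spec.noninferiority_margin >= spec.sd * 10 or spec.power <= spec.alpha:
        raise StatsError("margin/power outside the formula's plausible range")
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    z_b = sps.norm.ppf(spec.power)
    raw = ((z_a + z_b) * spec.sd / spec.noninferiority_margin) ** 2
    n = max(1, math.ceil(raw))
    n_vif = max(1, math.ceil(spec.variance_inflation_factor * raw))
    return SampleSizeResult(n, float(raw), n_vif)


# ---------------------------------------------------------------------------
# study-style summary
# ---------------------------------------------------------------------------


def summarize_outcomes(table: pd.DataFrame) -> dict:
    """Counts by jaw / tooth type / recession type and mean +/- SD of the
    outcome parameters, to 2 decimals; cRC percentage over eligible teeth."""
    if len(table) == 0:
        raise StatsError("empty study table")

    def _ms(col):
        vals = table[col].dropna().to_numpy(dtype=float) if col in table else np.array([])
        if len(vals) == 0:
            return None
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return {"mean": round(float(vals.mean()), 2), "sd": round(sd, 2), "n": len(vals)}

    counts = {
        "teeth": int(len(table)),
        "patients": int(table["patient_id"].nunique()) if "patient_id" in table else None,
    }
    notices = []
    for factor in FACTORS:
        if factor in table:
            vc = table[factor].value_counts().to_dict()
            counts[factor] = {str(k): int(v) for k, v in vc.items()}
            if len(vc) == 0:
                notices.append(f"empty stratum column {factor}")
    summary = {
        "counts": counts,
        "recession_depth_pre_mm": _ms("recession_depth_pre"),
        "recession_reduction_mm": _ms("recession_reduction"),
        "mean_root_coverage_pct": _ms("mrc_percent"),
        "thickness_gain_mm": _ms("thickness_gain"),
    }
    if "complete_coverage" in table:
        elig = table.dropna(subset=["complete_coverage"])
        if len(elig):
            summary["complete_root_coverage_pct"] = round(
                100.0 * float(elig["complete_coverage"].astype(bool).mean()), 2
            )
    if notices:
        summary["notices"] = notices
    return summary


# ---------------------------------------------------------------------------
# numeric table simulation (for calibration of the test level / coverage)
# ---------------------------------------------------------------------------


def simulate_study_table(
    n_patients: int = 19,
    n_teeth: int = 82,
    factor: str = "recession_type",
    levels: Sequence[str] = ("RT1", "RT2"),
    effects: Optional[dict] = None,
    patient_sd: float = 0.5,
    residual_sd: float = 1.0,
    outcome: str = "recession_reduction",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a clustered per-tooth outcome table (no meshes involved).

    Teeth are spread as evenly as possible over patients; each patient gets a
    Gaussian random intercept (``patient_sd``), each tooth a factor level
    drawn uniformly plus the level's ``effects`` shift and Gaussian residual
    noise.  Under ``effects=None`` the factor has no true effect -- the null
    configuration used to calibrate the test's type-I error.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    base = n_teeth // n_patients
    extra = n_teeth % n_patients
    rows = []
    tooth = 0
    for p in range(n_patients):
        intercept = rng.normal(0.0, patient_sd)
        for _ in range(base + (1 if p < extra else 0)):
            lev = levels[int(rng.integers(len(levels)))]
            y = intercept + effects.get(lev, 0.0) + rng.normal(0.0, residual_sd)
            rows.append(
                {
                    "patient_id": f"P{p + 1:02d}",
                    "tooth_id": f"T{tooth + 1:03d}",
                    factor: lev,
                    outcome: y,
                }
            )
            tooth += 1
    return pd.DataFrame(rows)
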