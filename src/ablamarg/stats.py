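"""Outcome and diagnostic statistics for margin-quantified cohorts.

Covers the analysis battery applied to a cohort of margin-quantified
tumors: threshold-sweep diagnostic performance (a tumor tests positive
when its minimal ablative margin lies *below* the cut-off), ROC/AUC,
Kaplan–Meier curves with the log-rank test across margin strata, uni-
and multivariable Cox proportional-hazards models of LTP-free survival,
and inter-software agreement (two-way random-effects single-measurement
absolute-agreement ICC plus median and median-absolute differences,
restricted to tumors where both software report a margin in [0, 10] mm).

Survival machinery is delegated to lifelines (Efron tie handling), the
ICC decomposition to pingouin, and the AUC to scikit-learn; the
threshold sweep and its exact-fraction bookkeeping are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score

from .synthetic import TumorRecord

__all__ = [
    "DiagnosticTable",
    "RocResult",
    "CoxFit",
    "KmLogrankResult",
    "AgreementStats",
    "diagnostic_table",
    "roc_auc",
    "km_logrank",
    "cox_fit",
    "icc_agreement",
    "mam_stratum",
]

Software = Literal["af", "safir"]

#: Default MAM thresholds (mm) for the sensitivity/FPR sweep.
DEFAULT_THRESHOLDS = tuple(range(0, 11))

#: Margin strata used for survival curves: residual, insufficient, adequate.
STRATA_LABELS = ("<=0", "(0,5)", ">=5")


class UndefinedRateError(ValueError):
    """Sensitivity or FPR undefined: a cohort with no events or no non-events."""


def _mam_of(record: TumorRecord, software: Software) -> int:
    if software == "af":
        return record.mam_af
    if software == "safir":
        return record.mam_safir
    raise ValueError(f"unknown software selector {software!r}")


def _round2(frac: Fraction) -> float:
    """Two-decimal reporting with half-up rounding of the exact fraction."""
    dec = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Threshold-sweep diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticTable:
    """Sensitivity and false-positive rate per MAM threshold.

    A tumor tests positive at threshold ``t`` iff its MAM < t. Exact
    fractions are kept alongside the 2-decimal rounded values.
    """

    thresholds: tuple[int, ...]
    sensitivity: dict[int, Fraction]
    fpr: dict[int, Fraction]

    def sensitivity_rounded(self, t: int) -> float:
        return _round2(self.sensitivity[t])

    def fpr_rounded(self, t: int) -> float:
        return _round2(self.fpr[t])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_mm": list(self.thresholds),
                "sensitivity": [self.sensitivity_rounded(t) for t in self.thresholds],
                "fpr": [self.fpr_rounded(t) for t in self.thresholds],
                "sensitivity_exact": [str(self.sensitivity[t]) for t in self.thresholds],
                "fpr_exact": [str(self.fpr[t]) for t in self.thresholds],
            }
        )


def diagnostic_table(
    records: Sequence[TumorRecord],
    software: Software,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> DiagnosticTable:
    """Sensitivity and FPR of "MAM < t" for each threshold t."""
    if not records:
        raise UndefinedRateError("no records")
    mam = np.array([_mam_of(r, software) for r in records])
    ltp = np.array([r.ltp for r in records], dtype=bool)
    n_pos = int(ltp.sum())
    n_neg = int((~ltp).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRateError(
            f"need both LTP and non-LTP cases (got {n_pos} events, {n_neg} non-events)"
        )
    sens: dict[int, Fraction] = {}
    fpr: dict[int, Fraction] = {}
    for t in thresholds:
        positive = mam < t
        sens[int(t)] = Fraction(int((positive & ltp).sum()), n_pos)
        fpr[int(t)] = Fraction(int((positive & ~ltp).sum()), n_neg)
    return DiagnosticTable(
        thresholds=tuple(int(t) for t in thresholds), sensitivity=sens, fpr=fpr
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95: tuple[float, float]
    curve: pd.DataFrame  # columns fpr, sensitivity, one row per threshold

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError("AUC must lie inside its confidence interval")


def roc_auc(
    records: Sequence[TumorRecord],
    software: Software,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Tie-aware AUC of -MAM for predicting LTP, with a bootstrap CI.

    The AUC equals the Mann–Whitney probability that a random LTP tumor
    has a smaller margin than a random non-LTP tumor (ties half-
    weighted). The 95% CI is a stratified nonparametric bootstrap
    (resampling events and non-events separately) with a fixed seed.
    """
    mam = np.array([_mam_of(r, software) for r in records], dtype=float)
    ltp = np.array([r.ltp for r in records], dtype=bool)
    if ltp.all() or not ltp.any():
        raise UndefinedRateError("AUC needs both LTP and non-LTP cases")
    score = -mam
    auc = float(roc_auc_score(ltp, score))

    rng = np.random.default_rng(seed)
    pos = score[ltp]
    neg = score[~ltp]
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        y = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        boots[b] = roc_auc_score(y, np.concatenate([bp, bn]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo = min(lo, auc)
    hi = max(hi, auc)

    table = diagnostic_table(records, software, DEFAULT_THRESHOLDS)
    curve = pd.DataFrame(
        {
            "threshold_mm": list(table.thresholds),
            "fpr": [float(table.fpr[t]) for t in table.thresholds],
            "sensitivity": [float(table.sensitivity[t]) for t in table.thresholds],
        }
    )
    return RocResult(auc=auc, ci95=(float(lo), float(hi)), curve=curve)


# ---------------------------------------------------------------------------
# Survival: Kaplan-Meier + log-rank, Cox PH
# ---------------------------------------------------------------------------

def mam_stratum(mam: float) -> str:
    """Margin stratum label: residual/none (<=0), insufficient (0,5), adequate (>=5)."""
    if mam <= 0:
        return STRATA_LABELS[0]
    if mam < 5:
        return STRATA_LABELS[1]
    return STRATA_LABELS[2]


@dataclass(frozen=True)
class KmLogrankResult:
    curves: dict[str, pd.DataFrame]  # per stratum: timeline, survival
    medians: dict[str, float]
    logrank_statistic: float
    logrank_p: float
    dropped_strata: tuple[str, ...] = ()


def km_logrank(
    records: Sequence[TumorRecord], software: Software = "af"
) -> KmLogrankResult:
    """Kaplan-Meier LTP-free survival per margin stratum, with log-rank test."""
    df = pd.DataFrame(
        {
            "time": [r.time_months for r in records],
            "event": [int(r.ltp) for r in records],
            "stratum": [mam_stratum(_mam_of(r, software)) for r in records],
        }
    )
    present = [s for s in STRATA_LABELS if (df["stratum"] == s).any()]
    dropped = tuple(s for s in STRATA_LABELS if s not in present)
    for s in dropped:
        warnings.warn(f"margin stratum {s} is empty and was dropped", stacklevel=2)
    if len(present) < 2:
        raise ValueError("log-rank needs at least two non-empty strata")

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for s in present:
        sub = df[df["stratum"] == s]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=s)
        curves[s] = pd.DataFrame(
            {
                "time_months": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[s].to_numpy(),
            }
        )
        medians[s] = float(kmf.median_survival_time_)
    sub = df[df["stratum"].isin(present)]
    lr = multivariate_logrank_test(sub["time"], sub["stratum"], sub["event"])
    return KmLogrankResult(
        curves=curves,
        medians=medians,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        dropped_strata=dropped,
    )


@dataclass(frozen=True)
class CoxFit:
    """Hazard ratios with Wald 95% CIs and p-values for one fitted model."""

    covariates: tuple[str, ...]
    hr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p: dict[str, float]
    log_likelihood: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        for name in self.covariates:
            lo, hi = self.ci95[name]
            if not (self.hr[name] > 0 and lo <= self.hr[name] <= hi):
                raise ValueError(f"inconsistent HR/CI for {name}")


_COVARIATE_GETTERS = {
    "mam_af": lambda r: r.mam_af,
    "mam_safir": lambda r: r.mam_safir,
    "size_cm": lambda r: r.size_cm,
    "subcapsular": lambda r: None if r.subcapsular is None else int(r.subcapsular),
    "perivascular": lambda r: None if r.perivascular is None else int(r.perivascular),
    "age": lambda r: r.age,
    "sex_male": lambda r: None if r.sex_male is None else int(r.sex_male),
    "prior_ctx": lambda r: None if r.prior_ctx is None else int(r.prior_ctx),
    "ablation_rfa": lambda r: None if r.ablation_rfa is None else int(r.ablation_rfa),
}


def _cox_frame(records: Sequence[TumorRecord], covariates: Sequence[str]) -> pd.DataFrame:
    data = {"time": [r.time_months for r in records], "event": [int(r.ltp) for r in records]}
    for name in covariates:
        if name not in _COVARIATE_GETTERS:
            raise ValueError(f"unknown covariate {name!r}")
        data[name] = [_COVARIATE_GETTERS[name](r) for r in records]
    df = pd.DataFrame(data)
    if df.isna().any().any():
        raise ValueError("missing covariate values in Cox input")
    return df


def _fit_one(df: pd.DataFrame, covariates: Sequence[str]) -> CoxFit:
    n_events = int(df["event"].sum())
    if n_events < 5 * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates; "
            "hazard ratios may be unstable",
            stacklevel=3,
        )
    cph = CoxPHFitter()  # lifelines default tie handling is Efron
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return CoxFit(
        covariates=tuple(covariates),
        hr={c: float(summary.loc[c, "exp(coef)"]) for c in covariates},
        ci95={
            c: (
                float(summary.loc[c, "exp(coef) lower 95%"]),
                float(summary.loc[c, "exp(coef) upper 95%"]),
            )
            for c in covariates
        },
        p={c: float(summary.loc[c, "p"]) for c in covariates},
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
    )


def cox_fit(
    records: Sequence[TumorRecord],
    covariates: Sequence[str],
    mode: Literal["univariable", "multivariable"] = "univariable",
) -> dict[str, CoxFit] | CoxFit:
    """Cox proportional-hazards LTP-free-survival model(s).

    Univariable mode fits one single-covariate model per requested
    covariate and returns a dict keyed by covariate; multivariable mode
    fits one joint model. Partial likelihood is maximized with Efron
    handling of tied event times; HRs carry Wald 95% CIs and p-values.
    """
    if mode == "univariable":
        return {
            name: _fit_one(_cox_frame(records, [name]), [name]) for name in covariates
        }
    if mode == "multivariable":
        return _fit_one(_cox_frame(records, covariates), covariates)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Inter-software agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementStats:
    icc: float
    icc_ci95: tuple[float, float]
    icc_defined: bool
    median_difference: float
    difference_iqr: tuple[float, float]
    median_abs_difference: float
    abs_difference_iqr: tuple[float, float]
    n_pairs: int


def icc_agreement(pairs: Sequence[tuple[float, float]]) -> AgreementStats:
    """Inter-software agreement on the comparable margin range.

    Pairs are restricted to tumors where both margins lie in [0, 10] mm
    (outside that range the coverage-style software reports no absolute
    value). The ICC is the two-way random-effects, absolute-agreement,
    single-measurement form with an F-distribution 95% CI; differences
    are A - B in mm.
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    keep = ((arr >= 0) & (arr <= 10)).all(axis=1)
    arr = arr[keep]
    if len(arr) < 2:
        raise ValueError("need at least 2 in-range pairs for agreement statistics")

    diff = arr[:, 0] - arr[:, 1]
    absdiff = np.abs(diff)
    d_q1, d_med, d_q3 = np.percentile(diff, [25, 50, 75])
    a_q1, a_med, a_q3 = np.percentile(absdiff, [25, 50, 75])

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(len(arr)), 2),
            "rater": np.tile(["A", "B"], len(arr)),
            "rating": arr.ravel(),
        }
    )
    icc_val = np.nan
    ci = (np.nan, np.nan)
    defined = float(np.var(arr.mean(axis=1))) > 0
    if defined:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pg.intraclass_corr(
                data=long, targets="subject", raters="rater", ratings="rating"
            )
        # single-measurement, two-way random, absolute agreement: labelled
        # ICC2 or ICC(A,1) depending on pingouin version
        mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
        row = table[mask].iloc[0]
        icc_val = float(row["ICC"])
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        ci = (float(row[ci_col][0]), float(row[ci_col][1]))
        defined = np.isfinite(icc_val)
    return AgreementStats(
        icc=icc_val,
        icc_ci95=ci,
        icc_defined=bool(defined),
        median_difference=float(d_med),
        difference_iqr=(float(d_q1), float(d_q3)),
        median_abs_difference=float(a_med),
        abs_difference_iqr=(float(a_q1), float(a_q3)),
        n_pairs=int(len(arr)),
    )
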