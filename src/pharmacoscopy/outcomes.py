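"""Clinical endpoint statistics for guided-treatment cohorts.

Implements the outcome analyses of a single-arm, patient-as-own-control
design: each patient's progression-free survival (PFS) and best overall
response under marker-guided therapy are compared with the same patient's
most recent prior regimen.

Conventions:

* overall response is coded CR / PR / SD / PD; a *responder* achieved CR
  or PR; the ordinal coding is 1=PD, 2=SD, 3=PR, 4=CR;
* PFS runs from first day of treatment to first reported progression or
  relapse; an ongoing response at the analysis cutoff is right-censored at
  the recorded PFS;
* clinical benefit for one patient means a PFS ratio (guided / prior)
  >= 1.3; the cohort null hypothesis is that at most 15% of patients reach
  that ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .aml_classifier import auroc

RESPONSE_LEVELS = ("PD", "SD", "PR", "CR")
ORDINAL = {"PD": 1, "SD": 2, "PR": 3, "CR": 4}
RESPONDER_CLASSES = frozenset({"CR", "PR"})

_RESPONSE_ALIASES = {
    "complete remission": "CR",
    "complete response": "CR",
    "partial response": "PR",
    "stable disease": "SD",
    "progressive disease": "PD",
}


@dataclass
class ClinicalRecord:
    """Per-patient outcome fields (one row of the clinical table)."""

    patient_id: str
    diagnosis: str
    overall_response: str
    pfs_weeks: float
    ongoing: bool
    previous_treatment_lines: int | None = None
    prior_response: str | None = None  # "responder" / "non-responder"
    prior_pfs_weeks: float | None = None
    i_pcy: float | None = None

    def __post_init__(self) -> None:
        if self.overall_response not in RESPONSE_LEVELS:
            raise ValueError(f"unknown overall_response {self.overall_response!r}")
        if not self.pfs_weeks > 0:
            raise ValueError("pfs_weeks must be > 0")

    @property
    def ordinal_response(self) -> int:
        return ORDINAL[self.overall_response]

    @property
    def is_responder(self) -> bool:
        return self.overall_response in RESPONDER_CLASSES


def normalize_response(value: str) -> str:
    v = str(value).strip()
    if v.upper() in RESPONSE_LEVELS:
        return v.upper()
    try:
        return _RESPONSE_ALIASES[v.lower()]
    except KeyError:
        raise ValueError(f"unrecognised response {value!r}") from None


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read a clinical outcome CSV (one row per patient).

    Required columns: patient_id, diagnosis, overall_response, pfs_weeks,
    ongoing_response.  Optional: previous_treatment_lines, prior_response,
    prior_pfs_weeks, i_pcy.  Long-hand response labels ("Complete
    remission") are accepted.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty clinical table: {path}")
    required = ["patient_id", "diagnosis", "overall_response", "pfs_weeks", "ongoing_response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        ongoing = str(row["ongoing_response"]).strip().lower() in {"yes", "true", "1"}
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                diagnosis=str(row["diagnosis"]),
                overall_response=normalize_response(row["overall_response"]),
                pfs_weeks=float(row["pfs_weeks"]),
                ongoing=ongoing,
                previous_treatment_lines=(
                    int(row["previous_treatment_lines"])
                    if "previous_treatment_lines" in df.columns
                    and pd.notna(row["previous_treatment_lines"])
                    else None
                ),
                prior_response=(
                    str(row["prior_response"])
                    if "prior_response" in df.columns and pd.notna(row["prior_response"])
                    else None
                ),
                prior_pfs_weeks=(
                    float(row["prior_pfs_weeks"])
                    if "prior_pfs_weeks" in df.columns and pd.notna(row["prior_pfs_weeks"])
                    else None
                ),
                i_pcy=(
                    float(row["i_pcy"])
                    if "i_pcy" in df.columns and pd.notna(row["i_pcy"])
                    else None
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMResult:
    times: np.ndarray          # event/censoring grid of the step function
    survival: np.ndarray       # S(t) at those times
    median: float | None       # None when S never reaches 0.5


def km_curve(times, events) -> KMResult:
    """Product-limit survival estimate and median.

    ``events[i]`` True means progression/death observed at ``times[i]``;
    False means censored there (e.g. an ongoing response).  The median is
    the smallest time with S(t) <= 0.5, or None when the curve never drops
    that far.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # smallest time with S(t) <= 0.5 (inclusive at exactly 0.5)
    hit = surv <= 0.5 + 1e-12
    median = float(grid[np.argmax(hit)]) if hit.any() else None
    return KMResult(times=grid, survival=surv, median=median)


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    hazard_ratio: float        # (O1/E1)/(O2/E2), group 1 over group 2
    hazard_ratio_mh: float     # Mantel-Haenszel exp((O1-E1)/V)


def logrank_hr(times1, events1, times2, events2) -> LogrankResult:
    """Log-rank (Mantel-Cox) test plus observed/expected hazard ratio.

    At each distinct event time the 2x2 risk table contributes observed
    and expected events under the null of equal hazards; the chi-square
    statistic is (O1-E1)^2 / V with hypergeometric variance V.  The
    reported hazard ratio is the O/E estimate (O1/E1)/(O2/E2); the
    Mantel-Haenszel variant exp((O1-E1)/V) is also returned.
    """
    t1 = np.asarray(times1, float); e1 = np.asarray(events1, bool)
    t2 = np.asarray(times2, float); e2 = np.asarray(events2, bool)
    all_t = np.r_[t1, t2]
    all_e = np.r_[e1, e2]
    grp = np.r_[np.ones(len(t1)), np.zeros(len(t2))]
    event_times = np.unique(all_t[all_e])
    O1 = E1 = O2 = E2 = V = 0.0
    for tau in event_times:
        at_risk = all_t >= tau
        n = at_risk.sum()
        n1 = (at_risk & (grp == 1)).sum()
        d = ((all_t == tau) & all_e).sum()
        d1 = ((all_t == tau) & all_e & (grp == 1)).sum()
        O1 += d1
        O2 += d - d1
        E1 += d * n1 / n
        E2 += d * (n - n1) / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    if E1 > 0 and E2 > 0 and O2 > 0:
        hr = (O1 / E1) / (O2 / E2)
    else:
        hr = math.inf if O1 > 0 else float("nan")
    hr_mh = math.exp((O1 - E1) / V) if V > 0 else float("nan")
    return LogrankResult(float(chi2), p, float(hr), float(hr_mh))


# ---------------------------------------------------------------------------
# Paired response analysis


@dataclass
class PairedResponseTable:
    """Paired responder counts: a both, b prior-only, c guided-only, d neither."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_records(cls, records: list[ClinicalRecord]) -> "PairedResponseTable":
        a = b = c = d = 0
        for r in records:
            if r.prior_response is None:
                raise ValueError(f"patient {r.patient_id} lacks prior_response")
            prior = r.prior_response == "responder"
            guided = r.is_responder
            if prior and guided:
                a += 1
            elif prior:
                b += 1
            elif guided:
                c += 1
            else:
                d += 1
        return cls(a, b, c, d)

    @classmethod
    def from_margins(
        cls, n: int, guided_responders: int, prior_responders: int, b: int
    ) -> "PairedResponseTable":
        """Reconstruct the paired table from its margins plus one discordant cell.

        ``b`` (respond prior only) pins the table down: a = prior - b,
        c = guided - a, d = n - a - b - c.
        """
        a = prior_responders - b
        c = guided_responders - a
        d = n - a - b - c
        if min(a, b, c, d) < 0:
            raise ValueError("inconsistent margins")
        return cls(a, b, c, d)


def mcnemar_one_sided(table: PairedResponseTable) -> tuple[float, float]:
    """One-sided McNemar test with continuity correction.

    chi2 = (max(|b - c| - 1, 0))^2 / (b + c); the one-sided p-value is half
    the chi-square(1) tail when the discordance favours guided therapy
    (c >= b), its complement otherwise; p = 1 when b + c = 0.
    """
    b, c = table.b, table.c
    if b + c == 0:
        return 0.0, 1.0
    stat = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    tail = float(stats.chi2.sf(stat, df=1)) / 2.0
    p = tail if c >= b else 1.0 - tail
    return float(stat), p


def contingency_odds_ratio(
    responders1: int, n1: int, responders2: int, n2: int, haldane: bool = False
) -> float:
    """Cross-product odds ratio of two response proportions.

    OR = (r1 * (n2 - r2)) / ((n1 - r1) * r2).  A zero cell yields inf
    (or nan for 0/0) unless ``haldane`` adds 0.5 to every cell.
    """
    r1, f1 = responders1, n1 - responders1
    r2, f2 = responders2, n2 - responders2
    if min(r1, f1, r2, f2) < 0:
        raise ValueError("negative cell count")
    if haldane:
        r1, f1, r2, f2 = r1 + 0.5, f1 + 0.5, r2 + 0.5, f2 + 0.5
    num, den = r1 * f2, f1 * r2
    if den == 0:
        return math.inf if num > 0 else float("nan")
    return num / den


# ---------------------------------------------------------------------------
# PFS ratio and i-PCY association


@dataclass
class PfsRatioResult:
    ratios: pd.Series                # per patient, guided / prior
    n_success: int                   # ratio >= threshold (inclusive)
    fraction: float
    p_value: float                   # exact binomial vs null fraction
    threshold: float
    null_fraction: float


def pfs_ratio_analysis(
    records: list[ClinicalRecord],
    threshold: float = 1.3,
    null_fraction: float = 0.15,
) -> PfsRatioResult:
    """Per-patient PFS ratios and the exact one-sided binomial cohort test.

    A ratio of exactly ``threshold`` counts as a success.  The null — that
    at most ``null_fraction`` of patients reach the threshold — is tested
    with a one-sided (greater) exact binomial test.
    """
    usable = [r for r in records if r.prior_pfs_weeks]
    if not usable:
        raise ValueError("no records with prior PFS")
    ratios = pd.Series(
        {r.patient_id: r.pfs_weeks / r.prior_pfs_weeks for r in usable}
    )
    n_success = int((ratios >= threshold).sum())
    p = stats.binomtest(n_success, len(ratios), null_fraction, alternative="greater").pvalue
    return PfsRatioResult(
        ratios=ratios,
        n_success=n_success,
        fraction=n_success / len(ratios),
        p_value=float(p),
        threshold=threshold,
        null_fraction=null_fraction,
    )


@dataclass
class IpcyAssociation:
    pearson_r: float
    p_value: float
    accuracy: float            # PD vs (PR u CR) at the best i-PCY cut
    best_cut: float
    auc: float
    n: int


def ipcy_outcome_association(records: list[ClinicalRecord]) -> IpcyAssociation:
    """Association between i-PCY scores and clinical response.

    Pearson correlation of i-PCY with the ordinal response over all
    scored patients, plus binary separation of progressive disease from
    responders (PR or CR; stable disease excluded from the binary task) at
    the accuracy-maximising i-PCY cut, with the ROC AUC over all cuts.
    """
    scored = [r for r in records if r.i_pcy is not None]
    if len(scored) < 3:
        raise ValueError("need >= 3 scored patients")
    x = np.array([r.i_pcy for r in scored])
    y_ord = np.array([r.ordinal_response for r in scored])
    r, p = stats.pearsonr(x, y_ord)

    binary = [s for s in scored if s.overall_response != "SD"]
    xb = np.array([s.i_pcy for s in binary])
    yb = np.array([1 if s.is_responder else 0 for s in binary])
    if yb.min() == yb.max():
        raise ValueError("need both PD and PR/CR patients for the binary task")
    cuts = np.r_[xb.min() - 1, (np.sort(xb)[:-1] + np.sort(xb)[1:]) / 2, xb.max() + 1]
    accs = [( (xb > c).astype(int) == yb ).mean() for c in cuts]
    best = int(np.argmax(accs))
    return IpcyAssociation(
        pearson_r=float(r),
        p_value=float(p),
        accuracy=float(accs[best]),
        best_cut=float(cuts[best]),
        auc=auroc(xb[yb == 1], xb[yb == 0]),
        n=len(scored),
    )


# ---------------------------------------------------------------------------
# Cohort endpoint summary


def endpoint_summary(records: list[ClinicalRecord]) -> dict:
    """Headline endpoints: responder counts, PD count, KM median PFS."""
    n = len(records)
    responders = sum(r.is_responder for r in records)
    pd_count = sum(r.overall_response == "PD" for r in records)
    km = km_curve([r.pfs_weeks for r in records], [not r.ongoing for r in records])
    return {
        "n_patients": n,
        "n_responders": responders,
        "n_progressive_disease": pd_count,
        "km_median_pfs_weeks": km.median,
        "n_censored": sum(r.ongoing for r in records),
    }
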