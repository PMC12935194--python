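"""Comparing computed scores against a reference score set.

The reference is typically the vigiGrade completeness score of the same
reports in another database, or scores from an individual manual assessment.
Per-report differences (own − reference) are summarised, agreement is
quantified by an intraclass correlation coefficient with a 95% confidence
interval, and reports deviating by at least ±0.3 are flagged and attributed
to the information categories on which the two sides disagree — first at
report level (sex, age, country, primary reporter, report type, comments),
then, only where the report level is concordant, at ADR-drug level (time to
onset, indication, outcome, dose).

The ICC defaults to the two-way random-effects, absolute-agreement,
single-measurement form ICC(2,1) — the natural model for the same reports
scored by two systems — with ICC(3,1) selectable for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scoring import CATEGORIES, CombinationScore, ReportScore

logger = logging.getLogger("vigiscore")

REPORT_LEVEL_CATEGORIES: tuple[str, ...] = (
    "sex", "age", "country", "primary_reporter", "report_type", "comments",
)
COMBINATION_LEVEL_CATEGORIES: tuple[str, ...] = (
    "time_to_onset", "indication", "outcome", "dose",
)

DEFAULT_DEVIATION_THRESHOLD = 0.3  # inclusive, both signs


@dataclass(frozen=True)
class IccResult:
    """An ICC estimate with its 95% CI, or an explicit degenerate marker."""

    estimate: float | None
    ci_lower: float | None
    ci_upper: float | None
    form: str
    n_pairs: int
    degenerate: bool = False
    reason: str | None = None


@dataclass
class ScoreComparison:
    """Paired per-report comparison of own scores against a reference."""

    pairs: pd.DataFrame  # report_id, own, reference, difference
    mean_difference: float
    sd_difference: float
    median_difference: float
    iqr_difference: tuple[float, float]
    icc: IccResult
    flagged: pd.DataFrame  # report_id, own, reference, difference, sign
    threshold: float
    use_best: bool
    n_unmatched: int


@dataclass
class DiscrepancyAttribution:
    """Category attribution for flagged reports.

    One row per flagged report in ``table`` (level, mismatching categories,
    attributable flag); per-category counts aggregated separately for the
    report and ADR-drug levels.
    """

    table: pd.DataFrame  # report_id, level, categories, attributable
    report_level_counts: dict[str, int]
    combination_level_counts: dict[str, int]
    n_report_level: int
    n_combination_level: int
    n_unattributable: int


def _two_way_mean_squares(arr: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the complete two-way targets x raters layout."""
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse


def compute_icc(
    pairs: Sequence[tuple[float, float]], form: str = "ICC2", alpha: float = 0.05
) -> IccResult:
    """ICC of paired scores from the two-way ANOVA mean squares.

    ``form`` is ``"ICC2"`` (two-way random effects, absolute agreement,
    single measurement — McGraw & Wong's ICC(A,1)) or ``"ICC3"`` (two-way
    mixed, consistency, ICC(C,1)).  The CI uses the standard F-distribution
    bounds for the chosen form.  With fewer than 3 pairs, or no variance at
    all, the result is an explicit degenerate marker rather than a number.
    """
    if form not in ("ICC2", "ICC3"):
        raise ValidationError(f"unsupported ICC form: {form!r}")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be a sequence of (own, reference) tuples")
    n, k = arr.shape
    if n < 3:
        return IccResult(None, None, None, form, n, degenerate=True,
                         reason="fewer than 3 pairs")
    if np.allclose(arr.var(), 0.0):
        return IccResult(None, None, None, form, n, degenerate=True,
                         reason="zero variance in both score sets")

    from scipy.stats import f as f_dist

    msr, msc, mse = _two_way_mean_squares(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "ICC2":
            est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            # McGraw & Wong (1996) CI for ICC(A,1)
            a = k * est / (n * (1.0 - est)) if est < 1.0 else np.inf
            b = 1.0 + k * est * (n - 1) / (n * (1.0 - est)) if est < 1.0 else np.inf
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den if v_den > 0 else np.nan
            f_l = f_dist.ppf(1 - alpha / 2, n - 1, v) if np.isfinite(v) else np.nan
            f_u = f_dist.ppf(1 - alpha / 2, v, n - 1) if np.isfinite(v) else np.nan
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
        else:
            est = (msr - mse) / (msr + (k - 1) * mse)
            df2 = (n - 1) * (k - 1)
            f_obs = msr / mse if mse > 0 else np.inf
            f_l = f_obs / f_dist.ppf(1 - alpha / 2, n - 1, df2)
            f_u = f_obs * f_dist.ppf(1 - alpha / 2, df2, n - 1)
            lo = (f_l - 1.0) / (f_l + k - 1.0)
            hi = (f_u - 1.0) / (f_u + k - 1.0)
    est = float(est)
    lo = float(lo) if np.isfinite(lo) else est
    hi = float(hi) if np.isfinite(hi) else est
    # the F-based bounds can numerically cross the point estimate at machine
    # precision; clamp so the interval always contains it
    lo, hi = min(lo, est, 1.0), min(max(hi, est), 1.0)
    return IccResult(est, lo, hi, form, n)


def compare_scores(
    own: Sequence[ReportScore],
    reference: Mapping[str, float],
    use_best: bool = False,
    threshold: float = DEFAULT_DEVIATION_THRESHOLD,
    icc_form: str = "ICC2",
) -> ScoreComparison:
    """Pair own report scores with a reference and summarise the differences.

    Reports without a reference value are excluded from pairing and logged.
    Differences are own − reference; flagging is inclusive at ±threshold.
    """
    own_values = {
        r.report_id: (r.best_score if use_best else r.mean_score) for r in own
    }
    matched = [rid for rid in own_values if rid in reference]
    n_unmatched = len(own_values) - len(matched)
    if n_unmatched:
        logger.info("%d report(s) without a reference score excluded from pairing",
                    n_unmatched)
    if not matched:
        raise ValidationError("no report identifiers shared with the reference scores")

    pairs = pd.DataFrame(
        {
            "report_id": matched,
            "own": [own_values[r] for r in matched],
            "reference": [float(reference[r]) for r in matched],
        }
    )
    pairs["difference"] = pairs["own"] - pairs["reference"]
    diffs = pairs["difference"].to_numpy()

    flagged = pairs[np.abs(diffs) >= threshold].copy()
    flagged["sign"] = np.where(flagged["difference"] > 0, "+", "-")

    return ScoreComparison(
        pairs=pairs,
        mean_difference=float(diffs.mean()),
        sd_difference=float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        median_difference=float(np.median(diffs)),
        iqr_difference=(
            float(np.percentile(diffs, 25)),
            float(np.percentile(diffs, 75)),
        ),
        icc=compute_icc(list(zip(pairs["own"], pairs["reference"])), form=icc_form),
        flagged=flagged.reset_index(drop=True),
        threshold=threshold,
        use_best=use_best,
        n_unmatched=n_unmatched,
    )


def presence_frame(combos: Sequence[CombinationScore]) -> pd.DataFrame:
    """Tabulate combination presence patterns for attribution."""
    return pd.DataFrame(
        [
            {
                "report_id": c.report_id,
                "drug_name": c.drug_name,
                "reaction_term": c.reaction_term,
                **c.presence.as_dict(),
            }
            for c in combos
        ]
    )


def _report_level_flags(frame: pd.DataFrame) -> pd.DataFrame:
    # report-level categories are constant within a report; take the first row
    return frame.groupby("report_id", sort=False)[list(REPORT_LEVEL_CATEGORIES)].first()


def attribute_discrepancies(
    flagged: Sequence[str],
    own_presence: pd.DataFrame,
    reference_presence: pd.DataFrame,
    ignore_categories: Sequence[str] = (),
) -> DiscrepancyAttribution:
    """Attribute flagged score deviations to mismatching categories.

    Each flagged report is attributed at exactly one level: the report level
    wins when any report-level category disagrees; only otherwise are the
    report's combinations compared (aligned on drug and reaction) at the
    ADR-drug level.  ``ignore_categories`` masks categories the reference
    cannot carry (e.g. ``("comments",)`` when the reference line listing has
    no free-text fields).  Flagged reports missing from the reference
    presence data are reported as unattributable, never raised.
    """
    unknown = sorted(set(ignore_categories) - set(CATEGORIES))
    if unknown:
        raise ValidationError(f"unknown categories in ignore_categories: {unknown}")
    report_cats = [c for c in REPORT_LEVEL_CATEGORIES if c not in ignore_categories]
    combo_cats = [c for c in COMBINATION_LEVEL_CATEGORIES if c not in ignore_categories]

    own_rep = _report_level_flags(own_presence)
    ref_rep = _report_level_flags(reference_presence)
    own_by_report = dict(tuple(own_presence.groupby("report_id", sort=False)))
    ref_by_report = dict(tuple(reference_presence.groupby("report_id", sort=False)))

    rows: list[dict[str, object]] = []
    report_counts = {c: 0 for c in REPORT_LEVEL_CATEGORIES}
    combo_counts = {c: 0 for c in COMBINATION_LEVEL_CATEGORIES}
    n_report = n_combo = n_unattributable = 0

    for rid in flagged:
        if rid not in own_rep.index or rid not in ref_rep.index:
            rows.append({"report_id": rid, "level": "unattributable",
                         "categories": "", "attributable": False})
            n_unattributable += 1
            continue

        mism = [c for c in report_cats if bool(own_rep.loc[rid, c]) != bool(ref_rep.loc[rid, c])]
        if mism:
            for c in mism:
                report_counts[c] += 1
            rows.append({"report_id": rid, "level": "report",
                         "categories": ";".join(mism), "attributable": True})
            n_report += 1
            continue

        own_c = own_by_report[rid].set_index(["drug_name", "reaction_term"])
        ref_c = ref_by_report[rid].set_index(["drug_name", "reaction_term"])
        shared = own_c.index.intersection(ref_c.index)
        combo_mism: set[str] = set()
        for key in shared:
            for c in combo_cats:
                if bool(own_c.loc[key, c]) != bool(ref_c.loc[key, c]):
                    combo_mism.add(c)
        if combo_mism:
            ordered = [c for c in COMBINATION_LEVEL_CATEGORIES if c in combo_mism]
            for c in ordered:
                combo_counts[c] += 1
            rows.append({"report_id": rid, "level": "adr_drug",
                         "categories": ";".join(ordered), "attributable": True})
            n_combo += 1
        else:
            rows.append({"report_id": rid, "level": "unattributable",
                         "categories": "", "attributable": False})
            n_unattributable += 1

    return DiscrepancyAttribution(
        table=pd.DataFrame(
            rows, columns=["report_id", "level", "categories", "attributable"]
        ),
        report_level_counts=report_counts,
        combination_level_counts=combo_counts,
        n_report_level=n_report,
        n_combination_level=n_combo,
        n_unattributable=n_unattributable,
    )


def read_reference_scores(path) -> dict[str, float]:
    """Read a two-column (report_id, score) reference csv."""
    frame = pd.read_csv(path, dtype={0: str})
    if frame.shape[1] < 2:
        raise ValidationError(
            f"reference score file needs two columns (report_id, score): {path}"
        )
    ids = frame.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"duplicate report identifiers in reference scores: {dupes}")
    return dict(zip(ids, frame.iloc[:, 1].astype(float)))
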