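"""Test-retest reliability analyses.

The quantitative validation toolkit for paired (occasion 1 / occasion 2)
administrations:

* ``icc_a1`` — single-measure intraclass correlation under a two-way mixed
  model with absolute agreement, ICC(A,1), for summed Likert module scores
  and day counts. The rater is the same person at test and retest, so
  absolute agreement (not consistency) is the right target.
* ``cohen_kappa`` — chance-corrected agreement for the categorical (yes/no)
  screeners, with percentile-bootstrap confidence intervals.
* ``band`` — the fair / good / excellent interpretation bands at .60 and
  .75 (or .80).
* ``reliability_table`` — the per-module table, with a log transform for the
  highly skewed agoraphobia summary scores and per-item kappas for the four
  trauma-exposure screeners.
* ``screening_consistency`` and ``flag_overendorsed`` — the threshold
  diagnostics used to tune screen-in cuts.

ICC(A,1) from the two-way ANOVA decomposition with n subjects and k=2
occasions::

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

where MSR, MSC, MSE are the rows (subjects), columns (occasions), and error
mean squares. The 95% CI is the McGraw & Wong F-based interval; the p-value
is the F test of H0: ICC = 0 (F = MSR/MSE on (n-1), (n-1)(k-1) df). Kappa
p-values are two-sided large-sample normal tests of H0: kappa = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel
from scipy import stats

from .errors import SageScreenError
from .model import Instrument, ResponseKind, ResponseValue, satisfied_atoms
from .scoring import module_summary_score, to_endorsement

Band = Literal["fair", "good", "excellent", "not_analyzable"]


class ReliabilityResult(BaseModel):
    """One row of a reliability table."""

    module_id: str
    label: str
    coefficient_type: Literal["icc_a1", "kappa"]
    estimate: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    band: Band = "not_analyzable"
    transform_applied: Literal["none", "log"] = "none"
    n: int = 0
    notes: str = ""


def band(estimate: float, cut_high: float = 0.75) -> Band:
    """Interpretation band: < .60 fair, [.60, cut_high) good, >= cut_high
    excellent. ``cut_high`` is .75 or .80 depending on the convention."""
    if not -1.0 <= estimate <= 1.0:
        raise ValueError(f"reliability estimate must lie in [-1, 1], got {estimate}")
    if cut_high not in (0.75, 0.80):
        raise ValueError("cut_high must be 0.75 or 0.80")
    if estimate < 0.60:
        return "fair"
    if estimate < cut_high:
        return "good"
    return "excellent"


def apply_transform(
    scores: Sequence[float] | np.ndarray,
    kind: Literal["none", "log"],
    min_possible: float = 0.0,
) -> np.ndarray:
    """Optionally log-transform skewed scores: x -> ln(x - min_possible + 1).

    ``min_possible`` is the scale floor (k for a k-item Likert summary), so a
    floor-valued score maps to 0. Raises on values below the floor.
    """
    x = np.asarray(scores, dtype=float)
    if kind == "none":
        return x
    shifted = x - min_possible + 1.0
    if np.any(shifted <= 0):
        raise ValueError("log transform requires scores >= min_possible")
    return np.log(shifted)


# ---------------------------------------------------------------------------
# ICC(A,1)


def _anova_decomposition(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of a two-way n x k layout, one observation per cell."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_a1(
    pairs: Sequence[Sequence[float]] | np.ndarray,
    cut_high: float = 0.75,
    transform: Literal["none", "log"] = "none",
    min_possible: float = 0.0,
    module_id: str = "",
    label: str = "",
) -> ReliabilityResult:
    """ICC(A,1) for an n x 2 score matrix with F-based 95% CI and p-value.

    Degenerate inputs (no between-subject variance, or constant data) yield a
    ``not_analyzable`` result rather than an exception.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be an n x 2 matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 paired observations")
    base = dict(module_id=module_id, label=label or module_id,
                coefficient_type="icc_a1", n=n, transform_applied=transform)
    x = apply_transform(x, transform, min_possible=min_possible)
    msr, msc, mse = _anova_decomposition(x)
    if np.allclose(x.var(), 0.0) or (msr <= 0 and mse <= 0):
        return ReliabilityResult(**base, notes="degenerate: no variance")
    if mse <= 1e-14 and msc <= 1e-14:
        # perfect absolute agreement with real between-subject variance
        return ReliabilityResult(**base, estimate=1.0, ci_low=1.0, ci_high=1.0,
                                 p_value=0.0, band=band(1.0, cut_high))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    # F test of H0: ICC = 0 (mse = 0 with an occasion effect gives F = inf)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(msr / mse, df1, df2)) if mse > 0 else 0.0
    # McGraw & Wong CI with Satterthwaite df
    alpha = 0.05
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    est = float(icc)  # reported unclipped; the raw ratio can undershoot -1 at tiny n
    return ReliabilityResult(
        **base,
        estimate=est,
        ci_low=float(lower),
        ci_high=float(upper),
        p_value=p,
        band=band(float(np.clip(est, -1.0, 1.0)), cut_high),
    )


# ---------------------------------------------------------------------------
# Cohen's kappa


def kappa_statistic(pairs: np.ndarray) -> float:
    """Point estimate of Cohen's kappa for an n x 2 categorical matrix.

    Returns ``nan`` for degenerate tables — a constant occasion column, a
    category carried by at most one respondent, or chance agreement 1 — the
    same rule the headline kappa applies, so bootstrap resamples of
    low-base-rate data are skipped consistently. Cheap path used inside the
    bootstrap loop.
    """
    a = np.asarray(pairs)
    if _kappa_degenerate(a) is not None:
        return float("nan")
    cats, codes = np.unique(a, return_inverse=True)
    m = len(cats)
    if m < 2:
        return float("nan")
    codes = codes.reshape(a.shape)
    n = a.shape[0]
    table = np.zeros((m, m))
    np.add.at(table, (codes[:, 0], codes[:, 1]), 1)
    po = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        return float("nan")
    return float((po - pe) / (1 - pe))


def _kappa_degenerate(a: np.ndarray) -> Optional[str]:
    """Reason the kappa is not analyzable, or None.

    Mirrors the behaviour reported for rare screeners: a constant occasion
    column, or a category carried by at most one respondent (empty cells and
    near-constants in the 2-way table), defeats the kappa.
    """
    if len(np.unique(a[:, 0])) < 2 or len(np.unique(a[:, 1])) < 2:
        return "constant occasion column"
    cats, counts = np.unique(a, return_counts=True)
    modal = cats[np.argmax(counts)]
    off_modal_respondents = int((a != modal).any(axis=1).sum())
    if off_modal_respondents <= 1:
        return "category endorsed by at most one respondent"
    return None


@dataclass
class BootstrapCI:
    low: Optional[float]
    high: Optional[float]
    n_degenerate: int = 0
    available: bool = True


def bootstrap_ci(
    pairs: Sequence[Sequence] | np.ndarray,
    statistic: Callable[[np.ndarray], float] = kappa_statistic,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile bootstrap CI with respondent-level resampling.

    Degenerate resamples (statistic returns nan) are skipped and counted; if
    more than half are degenerate the interval is reported unavailable —
    the behaviour seen for very-low-base-rate screeners.
    """
    if B < 200:
        raise ValueError("B must be at least 200")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(pairs)
    n = a.shape[0]
    values = []
    n_degenerate = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        v = statistic(a[idx])
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_degenerate += 1
        else:
            values.append(v)
    if n_degenerate > B // 2:
        return BootstrapCI(None, None, n_degenerate, available=False)
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(float(lo), float(hi), n_degenerate, available=True)


def cohen_kappa(
    pairs: Sequence[Sequence] | np.ndarray,
    cut_high: float = 0.75,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    module_id: str = "",
    label: str = "",
    bootstrap: bool = True,
) -> ReliabilityResult:
    """Cohen's kappa for paired categorical responses with bootstrap 95% CI.

    kappa = (p_o - p_e) / (1 - p_e); the p-value is a two-sided large-sample
    normal test of H0: kappa = 0 using the Fleiss null standard error.
    Degenerate tables give a ``not_analyzable`` result.
    """
    a = np.asarray(pairs)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("pairs must be an n x 2 matrix")
    n = a.shape[0]
    if n < 2:
        raise ValueError("kappa requires at least 2 paired observations")
    base = dict(module_id=module_id, label=label or module_id,
                coefficient_type="kappa", n=n)
    reason = _kappa_degenerate(a)
    if reason is not None:
        return ReliabilityResult(**base, notes=f"degenerate: {reason}")
    est = kappa_statistic(a)
    if math.isnan(est):
        return ReliabilityResult(**base, notes="degenerate: chance agreement 1")

    cats, codes = np.unique(a, return_inverse=True)
    codes = codes.reshape(a.shape)
    m = len(cats)
    table = np.zeros((m, m))
    np.add.at(table, (codes[:, 0], codes[:, 1]), 1)
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    pe = float(row @ col)
    # Fleiss null SE for the H0: kappa = 0 test
    se0 = math.sqrt(max(pe + pe**2 - float((row * col * (row + col)).sum()), 0.0)) / (
        (1 - pe) * math.sqrt(n)
    )
    p = 2 * float(stats.norm.sf(abs(est) / se0)) if se0 > 0 else float("nan")

    ci_low = ci_high = None
    notes = ""
    if bootstrap:
        ci = bootstrap_ci(a, kappa_statistic, B=B, seed=seed)
        if ci.available:
            ci_low, ci_high = ci.low, ci.high
        else:
            notes = "bootstrap CI unavailable (low base rate)"
    est = float(np.clip(est, -1.0, 1.0))
    return ReliabilityResult(
        **base, estimate=est, ci_low=ci_low, ci_high=ci_high, p_value=p,
        band=band(est, cut_high) if est >= -1 else "not_analyzable", notes=notes,
    )


# ---------------------------------------------------------------------------
# Paired studies


class RetestStudy(BaseModel):
    """Paired test-retest responses for a sample of respondents.

    Both occasions use the same instrument; ``occasion1[i]`` and
    ``occasion2[i]`` are respondent ``respondent_ids[i]``'s item→value maps.
    ``truth`` optionally carries the generating parameters of a simulated
    study (the ground-truth ledger).
    """

    respondent_ids: list[str]
    occasion1: list[dict[str, ResponseValue]]
    occasion2: list[dict[str, ResponseValue]]
    retest_interval_days: Optional[list[float]] = None
    truth: Optional[dict] = None

    def n(self) -> int:
        return len(self.respondent_ids)


def _complete_pairs_summary(
    study: RetestStudy, instr: Instrument, module_id: str, tag: Optional[str] = None
) -> np.ndarray:
    """n x 2 summary-score matrix over respondents with complete module data
    at both occasions."""
    rows = []
    for r1, r2 in zip(study.occasion1, study.occasion2):
        try:
            s1 = module_summary_score(instr, module_id, r1, symptom_tag=tag)
            s2 = module_summary_score(instr, module_id, r2, symptom_tag=tag)
        except SageScreenError:
            continue
        rows.append((s1, s2))
    return np.asarray(rows, dtype=float)


def _item_pairs(study: RetestStudy, item_id: str) -> np.ndarray:
    rows = [
        (r1[item_id], r2[item_id])
        for r1, r2 in zip(study.occasion1, study.occasion2)
        if item_id in r1 and item_id in r2
    ]
    return np.asarray(rows)


def reliability_table(
    study: RetestStudy,
    instr: Instrument,
    B: int = 2000,
    seed: int = 0,
    cut_high: float = 0.75,
) -> list[ReliabilityResult]:
    """Per-module test-retest coefficients, in instrument order.

    Pure-Likert modules get a summary-score ICC(A,1) (with the module's
    declared transform, and sub-scale rows for declared subscale tags); the
    day-count screener gets an ICC on raw counts; categorical modules get a
    kappa per always-administered yes/no screener item with bootstrap CIs.
    """
    out: list[ReliabilityResult] = []
    items = instr.items_by_id()
    ss = np.random.SeedSequence(seed)
    for module in instr.modules:
        kinds = {items[i].response_kind for i in module.screener_item_ids}
        name = module.category_name
        if kinds == {ResponseKind.likert5}:
            k = len(module.screener_item_ids)
            pairs = _complete_pairs_summary(study, instr, module.module_id)
            if len(pairs) < 3:
                out.append(ReliabilityResult(
                    module_id=module.module_id, label=name,
                    coefficient_type="icc_a1", n=len(pairs),
                    notes="fewer than 3 complete pairs"))
            else:
                out.append(icc_a1(
                    pairs, cut_high=cut_high, transform=module.summary_transform,
                    min_possible=float(k), module_id=module.module_id, label=name))
            for tag in module.subscale_tags:
                tag_k = sum(
                    1 for i in module.screener_item_ids
                    if items[i].symptom_tag == tag
                )
                sub = _complete_pairs_summary(study, instr, module.module_id, tag=tag)
                label = f"{name} – {tag}"
                if len(sub) < 3:
                    out.append(ReliabilityResult(
                        module_id=module.module_id, label=label,
                        coefficient_type="icc_a1", n=len(sub),
                        notes="fewer than 3 complete pairs"))
                else:
                    out.append(icc_a1(
                        sub, cut_high=cut_high, min_possible=float(tag_k),
                        module_id=module.module_id, label=label))
        elif kinds == {ResponseKind.count_days}:
            iid = module.screener_item_ids[0]
            pairs = _item_pairs(study, iid).astype(float)
            if len(pairs) < 3:
                out.append(ReliabilityResult(
                    module_id=module.module_id, label=name,
                    coefficient_type="icc_a1", n=len(pairs),
                    notes="fewer than 3 complete pairs"))
            else:
                out.append(icc_a1(pairs, cut_high=cut_high,
                                  module_id=module.module_id, label=name))
        else:
            # kappa per always-administered (ungated) categorical screener item
            yes_no_ids = [
                i for i in module.screener_item_ids
                if items[i].response_kind is ResponseKind.yes_no
                and not items[i].gate_item_ids
            ]
            for iid in yes_no_ids:
                pairs = _item_pairs(study, iid)
                label = name if len(yes_no_ids) == 1 else f"{name} – {items[iid].text}"
                child = np.random.default_rng(ss.spawn(1)[0])
                out.append(cohen_kappa(
                    pairs, cut_high=cut_high, B=B, seed=child,
                    module_id=module.module_id, label=label))
    return out


@dataclass
class ScreenConsistency:
    """Per-module screen-in agreement across the two occasions."""

    module_id: str
    both: int = 0
    one: int = 0
    neither: int = 0
    #: Screener items that alone carried a single-occasion screen-in — the
    #: threshold-sensitivity diagnostic that identified "I felt sad".
    single_occasion_items: list[str] = field(default_factory=list)


def screening_consistency(
    study: RetestStudy, instr: Instrument
) -> dict[str, ScreenConsistency]:
    """Counts of screen-in at both / one / neither occasion per module, plus
    the items solely responsible for each single-occasion screen-in."""
    from .administration import evaluate_screen_in

    out = {m.module_id: ScreenConsistency(module_id=m.module_id)
           for m in instr.modules}
    for r1, r2 in zip(study.occasion1, study.occasion2):
        for module in instr.modules:
            try:
                s1 = evaluate_screen_in(instr, module.module_id, r1)
                s2 = evaluate_screen_in(instr, module.module_id, r2)
            except SageScreenError:
                continue
            rec = out[module.module_id]
            if s1 and s2:
                rec.both += 1
            elif s1 or s2:
                rec.one += 1
                in_resp = r1 if s1 else r2
                atoms = satisfied_atoms(module.screen_in_rule, in_resp)
                if len(atoms) == 1 and atoms[0] not in rec.single_occasion_items:
                    rec.single_occasion_items.append(atoms[0])
            else:
                rec.neither += 1
    return out


def flag_overendorsed(
    sessions: Sequence[Mapping[str, ResponseValue]],
    instr: Instrument,
    threshold_fraction: float = 0.15,
) -> list[str]:
    """Items whose above-threshold endorsement rate strictly exceeds
    ``threshold_fraction`` across the sample (expert-review trigger).

    ``sessions`` are item→value maps; the denominator for each item is the
    number of sessions in which it was administered.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    items = instr.items_by_id()
    counts: dict[str, list[int]] = {}
    for resp in sessions:
        for iid, value in resp.items():
            if iid not in items:
                continue
            administered, endorsed = counts.setdefault(iid, [0, 0])
            counts[iid][0] = administered + 1
            counts[iid][1] = endorsed + int(to_endorsement(items[iid], value))
    flagged = [
        iid for iid, (administered, endorsed) in counts.items()
        if administered > 0 and endorsed / administered > threshold_fraction
    ]
    return [it.item_id for it in instr.items if it.item_id in set(flagged)]
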