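"""Synthetic respondents with known ground truth.

Two generator families make the whole pipeline testable without patient
data:

* **Session-level**: a ``RespondentProfile`` carries a latent per-module
  severity theta in [0, 1]; ``simulate_session`` drives the adaptive engine,
  drawing Likert levels by fixed cut-points on theta plus noise
  (graded-response style), yes/no screeners as Bernoulli(theta), and day
  counts as Binomial(timeframe, theta). The noise scale shrinks as
  sqrt(theta (1 - theta)), so theta = 0 is exactly an all-never/no/zero
  respondent and theta = 1 a ceiling respondent.
* **Study-level**: ``simulate_retest_pairs_continuous`` draws
  y_ij = b_i + e_ij with b ~ N(0, rho), e ~ N(0, 1 - rho) and no occasion
  effect, so the absolute-agreement ICC equals rho exactly;
  ``simulate_retest_pairs_binary`` draws i.i.d. pairs from the exchangeable
  2 x 2 joint with marginal prevalence p and agreement kappa.
  ``simulate_study`` assembles a full paired study whose module summary
  scores carry target reliabilities, recording every generating parameter in
  the study's ground-truth ledger.

Every generator is reproducible under a seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .administration import Response, Session, next_items, record_response, start_session
from .errors import SimulationError
from .model import Instrument, Item, ResponseKind
from .psychometrics import RetestStudy

#: Cut-points on the latent severity scale separating the five Likert levels.
LIKERT_CUTPOINTS = (0.2, 0.4, 0.6, 0.8)

#: Standard deviation of the latent response noise (scaled by
#: sqrt(theta (1 - theta)) so the floor and ceiling are deterministic).
LATENT_NOISE_SD = 0.35


class RespondentProfile(BaseModel):
    """Latent diagnostic profile of a synthetic respondent."""

    theta: dict[str, float]
    diagnosis_flags: list[str] = Field(default_factory=list)
    population: str = "nonclinical"  # nonclinical | clinical

    @model_validator(mode="after")
    def _check(self) -> "RespondentProfile":
        for mid, t in self.theta.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"theta[{mid!r}] must lie in [0, 1]")
        return self

    @classmethod
    def random(
        cls,
        instr: Instrument,
        rng: np.random.Generator,
        population: str = "nonclinical",
        flag_threshold: float = 0.7,
    ) -> "RespondentProfile":
        """Draw per-module severities from the population prior.

        Nonclinical: theta ~ Beta(1, 4) (mostly well); clinical:
        theta ~ Beta(2, 2). Modules with theta above ``flag_threshold`` carry
        a diagnosis flag (flags imply elevated severity by construction).
        """
        a, b = (1.0, 4.0) if population == "nonclinical" else (2.0, 2.0)
        theta = {m.module_id: float(rng.beta(a, b)) for m in instr.modules}
        flags = [mid for mid, t in theta.items() if t > flag_threshold]
        return cls(theta=theta, diagnosis_flags=flags, population=population)

    @classmethod
    def with_diagnoses(
        cls, instr: Instrument, modules: list[str], severity: float = 1.0
    ) -> "RespondentProfile":
        """A profile that "truly has" the given modules' diagnoses."""
        theta = {m.module_id: (severity if m.module_id in modules else 0.0)
                 for m in instr.modules}
        return cls(theta=theta, diagnosis_flags=list(modules), population="clinical")


def _draw_value(item: Item, theta: float, rng: np.random.Generator):
    noise = LATENT_NOISE_SD * np.sqrt(theta * (1 - theta))
    latent = theta + noise * rng.standard_normal() if noise > 0 else theta
    if item.response_kind is ResponseKind.likert5:
        level = 1 + int(np.sum(latent > np.asarray(LIKERT_CUTPOINTS)))
        return 6 - level if item.reverse_scored else level
    if item.response_kind is ResponseKind.yes_no:
        p = float(np.clip(latent, 0.0, 1.0))
        return bool(rng.random() < p)
    p = float(np.clip(latent, 0.0, 1.0))
    return int(rng.binomial(item.timeframe_days, p))


def simulate_session(
    instr: Instrument,
    profile: RespondentProfile,
    seed: int | np.random.Generator,
    session_id: str = "sim",
) -> Session:
    """Run one complete adaptive session for a synthetic respondent."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    session = start_session(instr, session_id=session_id)
    while True:
        queue = next_items(instr, session)
        if not queue:
            if session.phase != "complete":
                session.phase = "complete"
            break
        item = queue[0]
        value = _draw_value(item, profile.theta[item.module_id], rng)
        record_response(instr, session, Response(item_id=item.item_id, value=value))
        if session.phase == "complete":
            break
    return session


# ---------------------------------------------------------------------------
# Study-level generators with closed-form targets


def simulate_retest_pairs_continuous(
    n: int,
    true_icc: float,
    seed: int | np.random.Generator,
    occasion_shift: float = 0.0,
) -> np.ndarray:
    """n x 2 scores with absolute-agreement ICC exactly ``true_icc``.

    y_ij = b_i + e_ij + shift * 1[j=2], b ~ N(0, rho), e ~ N(0, 1 - rho).
    A nonzero ``occasion_shift`` breaks absolute agreement (but not
    consistency) — useful for stressing the distinction between the two ICC
    definitions.
    """
    if not 0.0 <= true_icc < 1.0:
        raise SimulationError("true_icc must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = rng.normal(0.0, np.sqrt(true_icc), size=(n, 1))
    e = rng.normal(0.0, np.sqrt(1.0 - true_icc), size=(n, 2))
    y = b + e
    y[:, 1] += occasion_shift
    return y


def binary_joint_probabilities(p: float, kappa: float) -> np.ndarray:
    """Exchangeable 2 x 2 cell probabilities [[p00, p01], [p10, p11]] with
    marginal prevalence ``p`` and Cohen agreement ``kappa``."""
    q = 1 - p
    p11 = p * p + kappa * p * q
    p00 = q * q + kappa * p * q
    p10 = p01 = p * q * (1 - kappa)
    cells = np.array([[p00, p01], [p10, p11]])
    if np.any(cells < -1e-12) or abs(cells.sum() - 1) > 1e-9:
        raise SimulationError(
            f"infeasible prevalence/kappa combination: p={p}, kappa={kappa}"
        )
    return np.clip(cells, 0.0, 1.0)


def simulate_retest_pairs_binary(
    n: int, prevalence: float, true_kappa: float, seed: int | np.random.Generator
) -> np.ndarray:
    """n x 2 boolean matrix of exchangeable paired Bernoulli draws."""
    if not 0.0 < prevalence < 1.0:
        raise SimulationError("prevalence must lie in (0, 1)")
    cells = binary_joint_probabilities(prevalence, true_kappa)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(4, size=n, p=cells.ravel() / cells.sum())
    return np.stack([(draws // 2).astype(bool), (draws % 2).astype(bool)], axis=1)


# ---------------------------------------------------------------------------
# Full paired studies


class ModuleTarget(BaseModel):
    """Generating reliability target for one module.

    Exactly one family applies: ``icc`` for Likert/count modules;
    ``item_kappas`` (item -> [kappa, prevalence]) for categorical screeners;
    ``stable_single_positive=True`` reproduces the degenerate case of a
    single respondent endorsing at both occasions.
    """

    icc: Optional[float] = None
    skewed: bool = False
    item_kappas: Optional[dict[str, tuple[float, float]]] = None
    stable_single_positive: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ModuleTarget":
        if self.icc is not None and not 0.0 <= self.icc < 1.0:
            raise ValueError("target icc must lie in [0, 1)")
        if self.item_kappas:
            for iid, (k, p) in self.item_kappas.items():
                if not -1.0 <= k <= 1.0:
                    raise ValueError(f"kappa target for {iid!r} outside [-1, 1]")
                if not 0.0 < p < 1.0:
                    raise ValueError(f"prevalence for {iid!r} outside (0, 1)")
        return self


class RetestSpec(BaseModel):
    """Specification of a simulated paired study."""

    n: int = 42
    seed: int = 0
    bootstrap_B: int = 2000
    module_targets: dict[str, ModuleTarget]
    retest_interval_days: float = 5.24


def default_retest_spec(n: int = 42, seed: int = 0) -> RetestSpec:
    """Study conditions emulating the instrument's initial nonclinical
    validation sample: n=42 returning within 7 days, with generating values
    set to the published per-module coefficients."""
    return RetestSpec(n=n, seed=seed, module_targets={
        "dep": ModuleTarget(icc=0.67),
        "mania": ModuleTarget(icc=0.50),
        "gad": ModuleTarget(icc=0.60),
        "panic": ModuleTarget(item_kappas={"panic_scr_attack": (0.86, 0.30)}),
        "agora": ModuleTarget(icc=0.90, skewed=True),
        "social": ModuleTarget(icc=0.83),
        "ocd": ModuleTarget(icc=0.68),
        "ptsd": ModuleTarget(item_kappas={
            "ptsd_scr_trauma_experienced": (0.86, 0.45),
            "ptsd_scr_trauma_witnessed": (0.60, 0.30),
            "ptsd_scr_trauma_close": (0.76, 0.50),
            "ptsd_scr_trauma_work": (0.79, 0.05),  # low base rate
        }),
        "adhd": ModuleTarget(icc=0.63),
        "psych": ModuleTarget(icc=0.72),
        "alcohol": ModuleTarget(icc=0.70),
        "cannabis": ModuleTarget(item_kappas={"cannabis_scr_use": (0.84, 0.25)}),
        "othersub": ModuleTarget(stable_single_positive=True),
    })


def _summaries_to_items(
    total: int, item_list: list[Item]
) -> dict[str, int]:
    """Distribute an integer summary score across k Likert items.

    Deterministic greedy split preserving sum(mirrored levels) == total;
    reverse items are stored mirrored. Item-level patterns are synthetic —
    only the summary carries signal.
    """
    k = len(item_list)
    base, rem = divmod(total - k, k)
    out = {}
    for j, item in enumerate(item_list):
        level = 1 + base + (1 if j < rem else 0)
        level = int(np.clip(level, 1, 5))
        out[item.item_id] = 6 - level if item.reverse_scored else level
    return out


def _latent_to_summary(x: np.ndarray, k: int, skewed: bool) -> np.ndarray:
    """Map standard-normal latents to integer summary scores in [k, 5k].

    Plain modules use the probability-integral transform (uniform marginal);
    skewed modules use a log-normal-style map concentrating mass near the
    floor, so the log transform is needed to de-skew."""
    if skewed:
        raw = np.exp(1.1 * x)            # right-skewed, floor-heavy
        frac = raw / (raw + np.exp(1.1 * 1.8))
    else:
        frac = stats.norm.cdf(x)
    return (k + np.floor(frac * (4 * k + 1)).clip(0, 4 * k)).astype(int)


def simulate_study(spec: RetestSpec, instr: Instrument) -> RetestStudy:
    """Generate a full paired study meeting the spec's module targets.

    Likert/count module summaries are driven by the exact-ICC latent model
    and distributed deterministically over items; categorical screeners are
    exchangeable kappa/prevalence draws. The returned study's ``truth`` field
    is the complete ground-truth ledger.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    items = instr.items_by_id()
    occ1: list[dict] = [dict() for _ in range(n)]
    occ2: list[dict] = [dict() for _ in range(n)]
    truth: dict = {"n": n, "seed": spec.seed, "modules": {}}

    for module in instr.modules:
        target = spec.module_targets.get(module.module_id)
        if target is None:
            raise SimulationError(f"no target for module {module.module_id!r}")
        t_rec: dict = {}
        scr_items = [items[i] for i in module.screener_item_ids]
        kinds = {it.response_kind for it in scr_items}
        if target.stable_single_positive:
            for i in range(n):
                v = i == 0  # one respondent, stable across occasions
                for it in scr_items:
                    occ1[i][it.item_id] = v
                    occ2[i][it.item_id] = v
            t_rec["stable_single_positive"] = True
        elif target.item_kappas is not None:
            gated = [it for it in scr_items if it.gate_item_ids]
            for it in scr_items:
                if it.item_id in target.item_kappas:
                    kap, prev = target.item_kappas[it.item_id]
                    pairs = simulate_retest_pairs_binary(n, prev, kap, rng)
                    for i in range(n):
                        occ1[i][it.item_id] = bool(pairs[i, 0])
                        occ2[i][it.item_id] = bool(pairs[i, 1])
                    t_rec[it.item_id] = {"kappa": kap, "prevalence": prev}
            # gated symptom screeners: answered only when a gate is open
            for it in gated:
                for i in range(n):
                    for occ in (occ1, occ2):
                        if any(occ[i].get(g) is True for g in it.gate_item_ids):
                            occ[i][it.item_id] = int(rng.integers(1, 6))
        elif kinds == {ResponseKind.count_days}:
            it = scr_items[0]
            x = simulate_retest_pairs_continuous(n, target.icc, rng)
            # quantile map onto a realistic drinking-days distribution
            counts = stats.binom(it.timeframe_days, 0.15).ppf(
                stats.norm.cdf(x)).astype(int)
            for i in range(n):
                occ1[i][it.item_id] = int(counts[i, 0])
                occ2[i][it.item_id] = int(counts[i, 1])
            t_rec["icc"] = target.icc
        else:
            if target.icc is None:
                raise SimulationError(
                    f"module {module.module_id!r} needs an icc target")
            subscale_tags = module.subscale_tags
            groups = (
                [[it for it in scr_items if it.symptom_tag == tag]
                 for tag in subscale_tags]
                if subscale_tags else [scr_items]
            )
            for group in groups:
                x = simulate_retest_pairs_continuous(n, target.icc, rng)
                totals = _latent_to_summary(x, len(group), target.skewed)
                for i in range(n):
                    occ1[i].update(_summaries_to_items(int(totals[i, 0]), group))
                    occ2[i].update(_summaries_to_items(int(totals[i, 1]), group))
            t_rec["icc"] = target.icc
            t_rec["skewed"] = target.skewed
        truth["modules"][module.module_id] = t_rec

    return RetestStudy(
        respondent_ids=[f"r{i:03d}" for i in range(n)],
        occasion1=occ1,
        occasion2=occ2,
        retest_interval_days=[spec.retest_interval_days] * n,
        truth=truth,
    )
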