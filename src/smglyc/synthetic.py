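"""Synthetic portal-cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so every stage is testable without access to any registry data.
The realization order is latent-first: per patient we draw the exposure X
(months with >= 1 patient-sent secure message), the moderator W (rurality,
0 = rural / 1 = urban), covariates, then the latent mediator M (DSMQ
composite) and latent outcome (percent time-in-control of HbA1c) from the
structural equations

    M   = i_m + a1*X + a2*W + a3*X*W + f'C + Normal(0, sigma_m),  clamped to [0, 10]
    TIC = i_y + c'*X + b*M           + g'C + Normal(0, sigma_y),  clamped to [0, 100]

and only then construct observable records that *measure* those latents:

* an HbA1c lab series whose Rosendaal time-in-control reproduces the
  latent TIC to within +/- 2 percentage points;
* a message log whose months-with-use metric recovers X exactly;
* DSMQ item responses whose composite score recovers M up to item
  quantization (empirically within 0.25 points).

Because the truth is known per patient, parameter recovery by the
moderated-mediation fit is a meaningful end-to-end check.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dsmq as dsmq_mod
from .errors import GenerationError, ValidationError
from .glycemic import HbA1cSeries, interpolate_daily, percent_time_in_control, year_length
from .io import TOPICS

# Default topic shares: the probability that a message-sending patient has
# at least one thread touching the topic over the year.  Diabetes content
# differs by rurality; the remaining topics do not.
DEFAULT_TOPIC_SHARES = {
    "diabetes": {"rural": 0.77, "urban": 0.67},
    "blood_pressure": 0.35,
    "cholesterol": 0.25,
    "physical_activity": 0.20,
    "diet_nutrition": 0.30,
    "mental_health": 0.25,
}


@dataclass(frozen=True)
class SMMonthsDist:
    """Distribution of months-with-use over the support {0..12}.

    The default is a beta-binomial matched to mean 6.7 and SD 3.1 months
    (a binomial cannot reach that much spread on 12 trials; the
    beta-binomial's extra-binomial variation can, without leaving the
    0-12 support).  An explicit 13-point pmf is also accepted.
    """

    kind: str = "beta_binomial"
    mean: float = 6.7
    sd: float = 3.1
    pmf: tuple = None

    N_MONTHS = 12

    def __post_init__(self):
        if self.kind == "pmf":
            p = np.asarray(self.pmf, dtype=float)
            if p.shape != (13,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise ValidationError("sm_months_dist: pmf must be 13 nonneg probs summing to 1")
        elif self.kind == "beta_binomial":
            self._ab()  # validates
        else:
            raise ValidationError(f"sm_months_dist: unknown kind {self.kind!r}")

    def _ab(self):
        n = self.N_MONTHS
        p = self.mean / n
        if not (0 < p < 1):
            raise ValidationError("sm_months_dist: mean must be in (0, 12)")
        var = self.sd**2
        base = n * p * (1 - p)
        if var <= base:
            raise ValidationError(
                "sm_months_dist: sd too small for a beta-binomial; use kind='pmf'"
            )
        rho = (var / base - 1) / (n - 1)
        if rho >= 1:
            raise ValidationError("sm_months_dist: sd too large for support 0..12")
        s = 1 / rho - 1
        return p * s, (1 - p) * s

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "pmf":
            return rng.choice(13, size=size, p=np.asarray(self.pmf, dtype=float))
        a, b = self._ab()
        return rng.binomial(self.N_MONTHS, rng.beta(a, b, size=size))


@dataclass(frozen=True)
class SyntheticConfig:
    """Structural truth and marginals for one synthetic cohort.

    Path coefficients default to the target-magnitude moderated-mediation
    truth (rural-level a-path 0.04, interaction -0.08, b-path 10.38) with
    rural coded 0 and urban 1; covariate marginals default to a veteran
    diabetes cohort (age ~ 66, ~10 primary-care visits/year, ~54% with
    income >= $35k).
    """

    n_patients: int = 446
    p_rural: float = 0.51
    a1: float = 0.04  # X -> M slope at W = 0 (rural)
    a2: float = 0.49  # W main effect on M
    a3: float = -0.08  # X*W interaction on M
    b: float = 10.38  # M -> Y slope
    c_prime: float = 0.09  # direct X -> Y slope
    i_m: float = 6.14  # mediator-model intercept
    i_y: float = -18.75  # outcome-model intercept
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": (0.02, -0.17),
            "visits": (0.01, 0.11),
            "income_band": (0.16, -1.99),
        }
    )
    sigma_m: float = 0.8
    sigma_y: float = 20.0
    sm_months_dist: SMMonthsDist = field(default_factory=SMMonthsDist)
    hba1c_measures_per_year: float = 4.0
    exposure_year: int = 2017
    outcome_year: int = 2018
    topic_shares: dict = field(default_factory=lambda: dict(DEFAULT_TOPIC_SHARES))
    # covariate marginals
    age_mean: float = 66.4
    age_sd: float = 7.5
    age_range: tuple = (34.0, 88.0)
    visits_mean: float = 10.1
    visits_sd: float = 7.8
    p_income_high: float = 0.536
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError(f"n_patients: must be >= 1, got {self.n_patients}")
        if not (0 <= self.p_rural <= 1):
            raise ValidationError(f"p_rural: must be in [0,1], got {self.p_rural}")
        if self.sigma_m <= 0:
            raise ValidationError(f"sigma_m: must be > 0, got {self.sigma_m}")
        if self.sigma_y <= 0:
            raise ValidationError(f"sigma_y: must be > 0, got {self.sigma_y}")
        if self.hba1c_measures_per_year < 2:
            raise ValidationError(
                f"hba1c_measures_per_year: must be >= 2, got {self.hba1c_measures_per_year}"
            )


@dataclass
class CohortDataset:
    """The four observable tables plus the generating truth."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    messages: pd.DataFrame
    dsmq: pd.DataFrame
    truth: dict

    def to_dir(self, outdir) -> dict:
        from pathlib import Path

        from .io import write_csv, write_json

        outdir = Path(outdir)
        paths = {
            "patients": write_csv(self.patients, outdir / "patients.csv"),
            "hba1c": write_csv(self.labs, outdir / "hba1c.csv"),
            "messages": write_csv(self.messages, outdir / "messages.csv"),
            "dsmq": write_csv(self.dsmq, outdir / "dsmq.csv"),
            "truth": write_json(self.truth, outdir / "truth.json"),
        }
        return paths


def _stage_rng(seed: int, stage: str, i: int | None = None) -> np.random.Generator:
    """Independent, process-stable stream per (seed, stage[, patient])."""
    tag = zlib.crc32(stage.encode("utf-8"))
    entropy = (seed, tag) if i is None else (seed, tag, i)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def trajectory_from_target_tic(
    target_tic: float,
    year: int,
    n_measurements: int,
    threshold: float = 8.0,
    seed=0,
    patient_id="p",
    max_retries: int = 5,
) -> HbA1cSeries:
    """Construct a lab series whose Rosendaal TIC hits ``target_tic`` +/- 2.

    The series is built around a single threshold crossing: measurements
    before the crossing day sit above the threshold, those after sit below,
    and (when feasible) one measurement sits exactly at the threshold on
    the crossing day, so the day count below threshold is controlled to
    day granularity.  The result is verified by the forward TIC
    computation; a failed verification is retried with fresh draws.
    """
    if not (0 <= target_tic <= 100):
        raise ValidationError(f"target_tic: must be in [0,100], got {target_tic}")
    if n_measurements < 2:
        raise ValidationError(f"n_measurements: must be >= 2, got {n_measurements}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ylen = year_length(year)
    jan1 = dt.date(year, 1, 1)

    for _ in range(max_retries):
        first = int(rng.integers(0, 21))
        last = int(rng.integers(ylen - 21, ylen))
        span = last - first + 1
        f = target_tic / 100.0

        days, vals = _build_crossing(rng, first, last, span, f, n_measurements, threshold)
        series = HbA1cSeries(
            patient_id, [(jan1 + dt.timedelta(days=int(d)), float(v)) for d, v in zip(days, vals)]
        )
        achieved = percent_time_in_control(interpolate_daily(series, year), threshold)
        if abs(achieved - target_tic) <= 2.0:
            return series
    raise GenerationError(
        f"could not hit TIC {target_tic} within +/-2 after {max_retries} attempts"
    )


def _build_crossing(rng, first, last, span, f, n, threshold):
    """Measurement days/values for one series; see trajectory_from_target_tic."""
    k = int(round(f * span))  # days to spend in control
    above = lambda size: threshold + rng.uniform(0.5, 2.5, size=size)
    below = lambda size: threshold - rng.uniform(0.5, 2.5, size=size)

    if k <= 0:
        days = _fill_days(rng, first, last, n)
        return days, above(len(days))
    if k >= span:
        days = _fill_days(rng, first, last, n)
        return days, below(len(days))

    c = last - k  # crossing day: strictly below threshold after c
    c = max(c, first)
    days = _fill_days(rng, first, last, n, must_include=(c,) if n >= 3 else ())
    days = np.asarray(days)
    vals = np.empty(len(days), dtype=float)
    vals[days < c] = above(int((days < c).sum()))
    vals[days > c] = below(int((days > c).sum()))
    vals[days == c] = threshold
    if c not in days:
        # steer the chord that straddles c so it crosses exactly at c
        left = int(np.max(days[days < c]))
        right = int(np.min(days[days > c]))
        tstar = (c - left) / (right - left)
        vals[days == left] = threshold + 2.0 * tstar
        vals[days == right] = threshold - 2.0 * (1.0 - tstar)
    return days, vals


def _fill_days(rng, first, last, n, must_include=()):
    """n strictly increasing day indices in [first, last] containing the
    endpoints and ``must_include``; n is reduced only if the span is tiny."""
    chosen = {first, last}
    chosen.update(int(m) for m in must_include if first <= m <= last)
    interior = np.arange(first + 1, last)
    interior = interior[~np.isin(interior, list(chosen))]
    need = min(n - len(chosen), len(interior))
    if need > 0:
        chosen.update(rng.choice(interior, size=need, replace=False).tolist())
    return np.array(sorted(chosen), dtype=int)


def generate_messages(
    patient_id,
    year: int,
    active_months,
    topic_probs: dict,
    seed=0,
    thread_start: int = 0,
) -> list:
    """Message rows for one patient-year.

    Guarantees >= 1 patient-sent message in each active month and none in
    any other month; each thread is a patient-initiated message plus an
    optional team reply, and per-message topic flags are Bernoulli draws
    from ``topic_probs``.
    """
    active_months = set(int(m) for m in active_months)
    if not active_months <= set(range(1, 13)):
        raise ValidationError(f"active_months: must be within 1..12, got {sorted(active_months)}")
    for t, p in topic_probs.items():
        if not (0 <= p <= 1):
            raise ValidationError(f"topic_probs[{t}]: must be in [0,1], got {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    tid = thread_start
    for month in sorted(active_months):
        n_threads = 1 + rng.poisson(0.7)
        ndays = (dt.date(year + (month == 12), month % 12 + 1, 1) - dt.date(year, month, 1)).days
        for _ in range(n_threads):
            day = int(rng.integers(1, ndays + 1))
            hour = int(rng.integers(7, 21))
            thread_id = f"{patient_id}-t{tid:04d}"
            tid += 1
            n_msgs = 1 + int(rng.random() < 0.7)  # patient opener + maybe team reply
            for j in range(n_msgs):
                flags = {t: int(rng.random() < topic_probs.get(t, 0.0)) for t in TOPICS}
                rows.append(
                    dict(
                        patient_id=patient_id,
                        thread_id=thread_id,
                        timestamp=dt.datetime(year, month, day, hour, min(59, j * 27)).isoformat(),
                        sender="patient" if j == 0 else "team",
                        **flags,
                    )
                )
    return rows


# DSMQ item realization -------------------------------------------------

_DELTAS = np.array(np.meshgrid(*[[-1, 0, 1]] * 4)).T.reshape(-1, 4)


def _dsmq_items_from_latent(m_latent: np.ndarray, instrument) -> np.ndarray:
    """Raw 16-item responses whose DSMQ composite approximates each latent M.

    Per subscale the integer item total nearest 3*M/10*n is taken, then a
    +/-1 local search over the four totals minimizes the composite error
    (residual quantization error is ~0.1 points at worst).  Totals are
    spread as evenly as possible over the subscale's items, and reverse
    items are un-reversed to raw form.
    """
    sub_items = [instrument.subscales[name] for name in instrument.subscales]
    sizes = np.array([len(s) for s in sub_items])
    mmax = instrument.max_transformed  # 3
    m = np.asarray(m_latent, dtype=float)
    n = len(m)

    target = m[:, None] / 10.0 * mmax * sizes[None, :]  # real-valued totals
    t0 = np.clip(np.round(target), 0, mmax * sizes[None, :])
    cand = t0[:, None, :] + _DELTAS[None, :, :]  # (n, 81, 4)
    cand = np.clip(cand, 0, (mmax * sizes)[None, None, :])
    comp = (cand / (mmax * sizes)[None, None, :] * 10.0).mean(axis=2)
    best = np.abs(comp - m[:, None]).argmin(axis=1)
    totals = cand[np.arange(n), best].astype(int)  # (n, 4)

    items = np.zeros((n, instrument.n_items), dtype=int)
    for s, item_nums in enumerate(sub_items):
        ns = sizes[s]
        base = totals[:, s] // ns
        rem = totals[:, s] % ns
        for j, item in enumerate(item_nums):
            items[:, item - 1] = base + (j < rem)
    unmapped = set(range(1, instrument.n_items + 1)) - {
        i for s in sub_items for i in s
    }
    for item in unmapped:  # general item: overall adherence level
        items[:, item - 1] = np.clip(np.round(m / 10.0 * mmax), 0, mmax).astype(int)
    for i in instrument.reverse_items:
        items[:, i - 1] = mmax - items[:, i - 1]
    return items


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate one cohort; deterministic given ``config.seed``."""
    n = config.n_patients
    rng = _stage_rng(config.seed, "patients")

    patient_ids = [f"P{i:05d}" for i in range(n)]
    x = config.sm_months_dist.sample(rng, n).astype(float)
    w = (rng.random(n) >= config.p_rural).astype(float)  # 1 = urban
    age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_range, size=n)
    # negative binomial with the configured mean/SD (overdispersed visit counts)
    mu, var = config.visits_mean, config.visits_sd**2
    r = mu**2 / (var - mu)
    visits = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
    income = (rng.random(n) < config.p_income_high).astype(float)
    cov = {"age": age, "visits": visits, "income_band": income}

    m_lin = config.i_m + config.a1 * x + config.a2 * w + config.a3 * x * w
    y_lin = config.i_y + config.c_prime * x
    for name, (bm, by) in config.covariate_effects.items():
        m_lin = m_lin + bm * cov[name]
        y_lin = y_lin + by * cov[name]
    m_latent = np.clip(m_lin + rng.normal(0, config.sigma_m, size=n), 0.0, 10.0)
    y_latent = np.clip(
        y_lin + config.b * m_latent + rng.normal(0, config.sigma_y, size=n), 0.0, 100.0
    )

    patients = pd.DataFrame(
        dict(
            patient_id=patient_ids,
            rurality_code=w.astype(int),
            age=np.round(age, 1),
            income_band=income.astype(int),
            visits=visits.astype(int),
        )
    )

    # labs: invert the target TIC into a measurement series per patient
    lab_rows = []
    n_meas = np.maximum(2, _stage_rng(config.seed, "labcount").poisson(
        config.hba1c_measures_per_year, size=n
    ))
    for i, pid in enumerate(patient_ids):
        series = trajectory_from_target_tic(
            float(y_latent[i]),
            config.outcome_year,
            int(n_meas[i]),
            seed=_stage_rng(config.seed, "labs", i),
            patient_id=pid,
        )
        for d, v in series.measurements:
            lab_rows.append((pid, d.isoformat(), round(v, 2)))
    labs = pd.DataFrame(lab_rows, columns=["patient_id", "date", "value"])

    # messages: active months realize X exactly
    msg_rows = []
    for i, pid in enumerate(patient_ids):
        mrng = _stage_rng(config.seed, "messages", i)
        months = mrng.choice(np.arange(1, 13), size=int(x[i]), replace=False)
        probs = _patient_topic_probs(config, w[i], int(x[i]))
        msg_rows.extend(
            generate_messages(pid, config.exposure_year, months, probs, seed=mrng)
        )
    messages = pd.DataFrame(
        msg_rows, columns=["patient_id", "thread_id", "timestamp", "sender", *TOPICS]
    )

    instrument = dsmq_mod.default_instrument()
    items = _dsmq_items_from_latent(m_latent, instrument)
    dsmq = pd.DataFrame(items, columns=dsmq_mod.ITEM_COLUMNS)
    dsmq.insert(0, "patient_id", patient_ids)

    truth = dict(
        config={
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        latent_m=np.round(m_latent, 6).tolist(),
        latent_tic=np.round(y_latent, 6).tolist(),
        x_months=x.astype(int).tolist(),
        rurality_code=w.astype(int).tolist(),
    )
    return CohortDataset(patients=patients, labs=labs, messages=messages, dsmq=dsmq, truth=truth)


def _patient_topic_probs(config: SyntheticConfig, w_i: float, x_i: int) -> dict:
    """Per-message topic probabilities calibrated so that the chance of
    >= 1 flagged thread over the year approximates the configured
    patient-level share (patients with no messages can carry no topic)."""
    if x_i == 0:
        return {t: 0.0 for t in TOPICS}
    expected_msgs = max(1.0, 1.7 * 1.7 * x_i)
    probs = {}
    for t in TOPICS:
        share = config.topic_shares.get(t, 0.0)
        if isinstance(share, dict):
            share = share["urban"] if w_i == 1 else share["rural"]
        probs[t] = 1.0 - (1.0 - share) ** (1.0 / expected_msgs)
    return probs
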