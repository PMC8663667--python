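"""First-stage moderated mediation with bootstrap percentile inference.

The structural model links an exposure X (months of secure-messaging use,
0-12), a mediator M (DSMQ composite, 0-10), an outcome Y (A1c%TIC, 0-100)
and a dichotomous moderator W (rurality), adjusting for covariates C:

    mediator model   M = i1 + a1*X + a2*W + a3*(X*W) + f'C + e_m
    outcome model    Y = i2 + c'*X + b*M          + g'C + e_y

The exposure->mediator path is moderated: the conditional indirect effect
of X on Y through M at moderator level w is ``(a1 + a3*w) * b``, and the
index of moderated mediation for a dichotomous W is the difference of the
two conditional indirect effects, ``a3 * b * (w_1 - w_0)``.  Inference on
the indirect effects uses nonparametric case-resampling bootstrap with
percentile confidence intervals; an effect is flagged significant when its
CI excludes zero.

The outcome model deliberately omits W and X*W (first-stage moderation
only); set ``ModelSpec.include_w_in_outcome`` to add them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .errors import (
    BootstrapInstabilityError,
    InsufficientDataError,
    ModerationUndefinedError,
    SingularDesignError,
    ValidationError,
)

_RCOND = 1e-10  # relative rank tolerance for singular-design detection


@dataclass(frozen=True)
class ModelSpec:
    """Names, codings and bootstrap settings for one moderated-mediation fit."""

    x_name: str = "sm_months"
    m_name: str = "dsmq_composite"
    y_name: str = "a1c_tic_percent"
    w_name: str = "rurality_code"
    covariate_names: tuple = ("age", "visits", "income_band")
    w_coding: tuple = (0, 1)  # (rural code, urban code); must differ
    w_labels: tuple = ("rural", "urban")
    include_w_in_outcome: bool = False
    n_boot: int = 5000
    ci_level: float = 0.95
    max_unusable_fraction: float = 0.10  # bootstrap instability guard
    seed: int = 0

    def __post_init__(self):
        if self.w_coding[0] == self.w_coding[1]:
            raise ValidationError("w_coding: the two moderator codes must differ")
        if not (0 < self.ci_level < 1):
            raise ValidationError(f"ci_level: must be in (0,1), got {self.ci_level}")
        if self.n_boot < 1:
            raise ValidationError(f"n_boot: must be >= 1, got {self.n_boot}")


def _find_collinear(X: np.ndarray, names) -> list:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d[0] * max(X.shape) * np.finfo(float).eps * 100 if d[0] > 0 else 0.0
    bad = [names[piv[i]] for i in range(len(d)) if d[i] <= tol]
    return bad or list(names)


def fit_ols(y, X: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Ordinary least squares with classical inference.

    Parameters
    ----------
    y : array-like, outcome values (complete cases).
    X : DataFrame of design columns, including an explicit constant if one
        is wanted.

    Returns a coefficient table indexed by column name with columns
    ``coef, se, t, p, ci_low, ci_high`` (two-tailed t tests, n - p df).
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise InsufficientDataError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(Xv) < p:
        raise SingularDesignError(_find_collinear(Xv, list(X.columns)))
    res = sm.OLS(y, Xv).fit()
    ci = res.conf_int(alpha=1 - ci_level)
    return pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=list(X.columns),
    )


@dataclass
class MediationFit:
    """Fitted mediator/outcome models and the derived indirect effects."""

    spec: ModelSpec
    mediator_model: pd.DataFrame
    outcome_model: pd.DataFrame
    conditional_indirect: dict  # w label -> point estimate
    index_mm: float
    n_used: int

    @property
    def a1(self) -> float:
        return float(self.mediator_model.loc[self.spec.x_name, "coef"])

    @property
    def a3(self) -> float:
        return float(self.mediator_model.loc["x_w", "coef"])

    @property
    def b(self) -> float:
        return float(self.outcome_model.loc[self.spec.m_name, "coef"])


def _designs(data: pd.DataFrame, spec: ModelSpec):
    """Complete-case arrays and named design frames for the two models."""
    cols = [spec.x_name, spec.m_name, spec.y_name, spec.w_name, *spec.covariate_names]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"data: missing columns {missing}")
    d = data[cols].dropna()
    if d[spec.w_name].nunique() < 2:
        raise ModerationUndefinedError(
            f"moderator {spec.w_name!r} takes fewer than 2 distinct values"
        )
    x = d[spec.x_name].to_numpy(float)
    w = d[spec.w_name].to_numpy(float)
    Xm = pd.DataFrame(
        {
            "const": 1.0,
            spec.x_name: x,
            spec.w_name: w,
            "x_w": x * w,
            **{c: d[c].to_numpy(float) for c in spec.covariate_names},
        }
    )
    Xy_cols = {"const": 1.0, spec.x_name: x, spec.m_name: d[spec.m_name].to_numpy(float)}
    if spec.include_w_in_outcome:
        Xy_cols[spec.w_name] = w
        Xy_cols["x_w"] = x * w
    Xy_cols.update({c: d[c].to_numpy(float) for c in spec.covariate_names})
    Xy = pd.DataFrame(Xy_cols)
    return d, Xm, Xy


def conditional_indirect_effect(a1: float, a3: float, b: float, w_value: float) -> float:
    """Indirect effect of X on Y through M at moderator value w: (a1 + a3*w) * b."""
    return (a1 + a3 * w_value) * b


def index_of_moderated_mediation(a3: float, b: float, w_coding=(0, 1)) -> float:
    """Difference of the conditional indirect effects across the two W levels."""
    w0, w1 = w_coding
    return a3 * b * (w1 - w0)


def fit_moderated_mediation(data: pd.DataFrame, spec: ModelSpec) -> MediationFit:
    """Point estimates for the moderated-mediation model (no bootstrap)."""
    d, Xm, Xy = _designs(data, spec)
    observed_w = set(np.unique(d[spec.w_name].to_numpy(float)))
    expected_w = set(float(c) for c in spec.w_coding)
    if not observed_w <= expected_w:
        raise ValidationError(
            f"data: moderator values {sorted(observed_w)} do not match "
            f"w_coding {spec.w_coding}"
        )
    med = fit_ols(d[spec.m_name], Xm, spec.ci_level)
    out = fit_ols(d[spec.y_name], Xy, spec.ci_level)
    a1 = float(med.loc[spec.x_name, "coef"])
    a3 = float(med.loc["x_w", "coef"])
    b = float(out.loc[spec.m_name, "coef"])
    cond = {
        label: conditional_indirect_effect(a1, a3, b, w)
        for label, w in zip(spec.w_labels, spec.w_coding)
    }
    return MediationFit(
        spec=spec,
        mediator_model=med,
        outcome_model=out,
        conditional_indirect=cond,
        index_mm=index_of_moderated_mediation(a3, b, spec.w_coding),
        n_used=len(d),
    )


def _batched_coefs(X: np.ndarray, y: np.ndarray, idx: np.ndarray):
    """Per-resample OLS coefficients for all resamples at once.

    Returns (coefs (B,p), ok (B,) bool); resamples whose Gram matrix is
    ill-conditioned are flagged not-ok and excluded by the caller.
    """
    Xb = X[idx]  # (B, n, p)
    yb = y[idx]  # (B, n)
    G = np.einsum("bni,bnj->bij", Xb, Xb)
    r = np.einsum("bni,bn->bi", Xb, yb)
    ok = np.linalg.cond(G) < 1.0 / _RCOND
    p = X.shape[1]
    coefs = np.full((len(idx), p), np.nan)
    if ok.any():
        coefs[ok] = np.linalg.solve(G[ok], r[ok][:, :, None])[:, :, 0]
    return coefs, ok


@dataclass
class BootstrapResult:
    """Percentile CIs for the conditional indirect effects and the index."""

    conditional_ci: dict  # w label -> (low, high)
    index_ci: tuple
    significant: dict  # statistic name -> bool (CI excludes 0)
    n_boot_completed: int
    n_boot_skipped: int
    draws_index: np.ndarray = field(repr=False, default=None)


def bootstrap_cis(data: pd.DataFrame, spec: ModelSpec) -> BootstrapResult:
    """Nonparametric case-resampling bootstrap for the indirect effects.

    Rows are resampled with replacement at the original n; both models are
    refit per resample; CIs are percentile intervals of the resampled
    statistics.  Resamples with singular designs are skipped and counted;
    more than ``spec.max_unusable_fraction`` (default 10%) skipped raises
    :class:`BootstrapInstabilityError`.  Tiny-n datasets with a full
    interaction design are intrinsically above the default (at n = 7 with a
    3/4 moderator split about a third of all resamples are singular), so
    exhaustive-enumeration comparisons raise the threshold explicitly.
    """
    d, Xm, Xy = _designs(data, spec)
    n = len(d)
    Xm_v = Xm.to_numpy(float)
    Xy_v = Xy.to_numpy(float)
    m_v = d[spec.m_name].to_numpy(float)
    y_v = d[spec.y_name].to_numpy(float)
    ix_a1 = list(Xm.columns).index(spec.x_name)
    ix_a3 = list(Xm.columns).index("x_w")
    ix_b = list(Xy.columns).index(spec.m_name)

    rng = np.random.default_rng(spec.seed)
    alpha = 1 - spec.ci_level
    a1s, a3s, bs = [], [], []
    skipped = 0
    # chunked so memory stays modest at large n_boot
    remaining = spec.n_boot
    while remaining > 0:
        B = min(remaining, 2000)
        remaining -= B
        idx = rng.integers(0, n, size=(B, n))
        cm, okm = _batched_coefs(Xm_v, m_v, idx)
        cy, oky = _batched_coefs(Xy_v, y_v, idx)
        ok = okm & oky
        skipped += int(B - ok.sum())
        a1s.append(cm[ok, ix_a1])
        a3s.append(cm[ok, ix_a3])
        bs.append(cy[ok, ix_b])
    if skipped > spec.max_unusable_fraction * spec.n_boot:
        raise BootstrapInstabilityError(skipped, spec.n_boot)
    a1b = np.concatenate(a1s)
    a3b = np.concatenate(a3s)
    bb = np.concatenate(bs)

    w0, w1 = spec.w_coding
    cond_draws = {
        spec.w_labels[0]: (a1b + a3b * w0) * bb,
        spec.w_labels[1]: (a1b + a3b * w1) * bb,
    }
    index_draws = a3b * bb * (w1 - w0)
    q = [alpha / 2, 1 - alpha / 2]
    cond_ci = {k: tuple(np.quantile(v, q)) for k, v in cond_draws.items()}
    index_ci = tuple(np.quantile(index_draws, q))
    sig = {f"indirect_{k}": not (lo <= 0.0 <= hi) for k, (lo, hi) in cond_ci.items()}
    sig["index_mm"] = not (index_ci[0] <= 0.0 <= index_ci[1])
    return BootstrapResult(
        conditional_ci=cond_ci,
        index_ci=index_ci,
        significant=sig,
        n_boot_completed=int(len(index_draws)),
        n_boot_skipped=skipped,
        draws_index=index_draws,
    )


@dataclass
class MediationReport:
    """Point estimates plus bootstrap inference, with a printable table."""

    fit: MediationFit
    boot: BootstrapResult

    def to_dict(self) -> dict:
        f, b = self.fit, self.boot
        return {
            "n_used": f.n_used,
            "mediator_model": f.mediator_model.round(6).to_dict(orient="index"),
            "outcome_model": f.outcome_model.round(6).to_dict(orient="index"),
            "conditional_indirect": {
                k: {
                    "estimate": f.conditional_indirect[k],
                    "ci_low": b.conditional_ci[k][0],
                    "ci_high": b.conditional_ci[k][1],
                    "significant": b.significant[f"indirect_{k}"],
                }
                for k in f.conditional_indirect
            },
            "index_of_moderated_mediation": {
                "estimate": f.index_mm,
                "ci_low": b.index_ci[0],
                "ci_high": b.index_ci[1],
                "significant": b.significant["index_mm"],
            },
            "n_boot_completed": b.n_boot_completed,
            "n_boot_skipped": b.n_boot_skipped,
        }

    def to_text(self) -> str:
        f, b = self.fit, self.boot
        lines = [f"Moderated mediation (n = {f.n_used})", ""]

        def block(title, table):
            lines.append(title)
            for name, row in table.iterrows():
                lines.append(
                    f"  {name:<28s} {row['coef']:>8.2f} "
                    f"({row['ci_low']:.2f} to {row['ci_high']:.2f})  p={row['p']:.3f}"
                )
            lines.append("")

        block(f"Model to predict {f.spec.m_name}", f.mediator_model)
        block(f"Model to predict {f.spec.y_name}", f.outcome_model)
        lines.append("Conditional indirect effects (bootstrap percentile CI)")
        for k, est in f.conditional_indirect.items():
            lo, hi = b.conditional_ci[k]
            star = "*" if b.significant[f"indirect_{k}"] else ""
            lines.append(f"  {k:<28s} {est:>8.2f} ({lo:.2f} to {hi:.2f}){star}")
        lo, hi = b.index_ci
        star = "*" if b.significant["index_mm"] else ""
        lines.append(
            f"  {'index of moderated mediation':<28s} {f.index_mm:>8.2f} "
            f"({lo:.2f} to {hi:.2f}){star}"
        )
        return "\n".join(lines) + "\n"


def run_moderated_mediation(data: pd.DataFrame, spec: ModelSpec) -> MediationReport:
    """Fit the model and attach bootstrap CIs; identities are re-asserted.

    The conditional-indirect and index identities are exact algebra on the
    fitted coefficients, so they are checked on every run as an internal
    consistency guard.
    """
    fit = fit_moderated_mediation(data, spec)
    labels = fit.spec.w_labels
    expected = {
        lab: conditional_indirect_effect(fit.a1, fit.a3, fit.b, w)
        for lab, w in zip(labels, spec.w_coding)
    }
    for lab in labels:
        assert abs(fit.conditional_indirect[lab] - expected[lab]) < 1e-12
    assert (
        abs(fit.index_mm - (fit.conditional_indirect[labels[1]] - fit.conditional_indirect[labels[0]]))
        < 1e-12
    )
    boot = bootstrap_cis(data, spec)
    return MediationReport(fit=fit, boot=boot)


def sensitivity_spec(spec: ModelSpec, x_name: str) -> ModelSpec:
    """Same-year sensitivity variant: swap in the same-year exposure column."""
    return replace(spec, x_name=x_name)
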