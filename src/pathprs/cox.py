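"""Cox proportional-hazards estimation for case-cohort data.

Implements the Prentice case-cohort partial likelihood: subcohort members
are at risk over their whole follow-up, while cases sampled from outside
the subcohort enter the risk set only at their own failure time.  A
Barlow-weighted variant (subcohort person-time up-weighted by the inverse
sampling fraction) is available behind :class:`RiskSetPolicy`.  Variance
comes both from the inverse information and from a score-residual sandwich
clustered on participant id — the "robust variance option" appropriate for
the extra variability introduced by sampling the subcohort.

Tie handling follows Efron by default (Breslow available).  Estimation is
Newton-Raphson with step-halving on the exact gradient/Hessian; risk-set
sums are computed with suffix cumulative sums over event times, so a fit
costs O((n + k) p^2) for k distinct event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RiskSetPolicy:
    """Estimator variant and tie method, declared once per analysis run.

    ``variant="prentice"`` (default): unweighted Prentice risk sets.
    ``variant="barlow"``: subcohort contributions weighted by
    ``1/sampling_fraction`` (must be supplied); non-subcohort cases keep
    weight 1 at their failure time.
    """

    variant: str = "prentice"
    ties: str = "efron"
    sampling_fraction: float | None = None

    def __post_init__(self):
        if self.variant not in ("prentice", "barlow"):
            raise ValueError(f"unknown estimator variant {self.variant!r}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie method {self.ties!r}")
        if self.variant == "barlow" and not (
            self.sampling_fraction and 0 < self.sampling_fraction <= 1
        ):
            raise ValueError("barlow variant requires sampling_fraction in (0, 1]")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """Result of a (case-cohort) Cox partial-likelihood fit."""

    names: list[str]
    params: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    loglik: float
    n: int
    n_events: int
    iterations: int
    converged: bool
    policy: RiskSetPolicy
    # internals kept for diagnostics (Schoenfeld residuals etc.)
    _diag: dict = field(default_factory=dict, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model))

    @property
    def robust_se(self) -> np.ndarray:
        # the sandwich is PSD in exact arithmetic; clip the tiny negative
        # diagonals an ill-conditioned information matrix can produce
        return np.sqrt(np.maximum(np.diag(self.cov_robust), 0.0))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """HR confidence limits from the robust SE: exp(beta +- z * rse)."""
        z = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(over="ignore"):  # inf bounds on degenerate contrasts
            lo = np.exp(self.params - z * self.robust_se)
            hi = np.exp(self.params + z * self.robust_se)
        return np.column_stack([lo, hi])

    def p_values(self) -> np.ndarray:
        z = self.params / self.robust_se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": self.hr,
                "se": self.se,
                "robust_se": self.robust_se,
                "hr_ci_low": ci[:, 0],
                "hr_ci_high": ci[:, 1],
                "p": self.p_values(),
            },
            index=pd.Index(self.names, name="covariate"),
        )


def _risk_sums(ut, p, stop_A, w_A, x_A, k_B, w_B, x_B):
    """S0/S1/S2 at each distinct event time.

    Subcohort (group A) rows are at risk while ``stop >= t``; computed as
    suffix sums over A rows sorted by stop time.  Case-only (group B) rows
    are at risk exactly at their own failure time ``ut[k_B]``.
    """
    order = np.argsort(stop_A, kind="stable")
    sA = stop_A[order]
    wA = w_A[order]
    xA = x_A[order]
    wx = wA[:, None] * xA
    wxx = wx[:, :, None] * xA[:, None, :]
    # suffix sums: total - prefix
    cw = np.concatenate([[0.0], np.cumsum(wA)])
    cwx = np.concatenate([np.zeros((1, p)), np.cumsum(wx, axis=0)])
    cwxx = np.concatenate([np.zeros((1, p, p)), np.cumsum(wxx, axis=0)])
    idx = np.searchsorted(sA, ut, side="left")  # first A row with stop >= t
    S0 = cw[-1] - cw[idx]
    S1 = cwx[-1] - cwx[idx]
    S2 = cwxx[-1] - cwxx[idx]
    if len(k_B):
        np.add.at(S0, k_B, w_B)
        np.add.at(S1, k_B, w_B[:, None] * x_B)
        np.add.at(S2, k_B, (w_B[:, None] * x_B)[:, :, None] * x_B[:, None, :])
    return S0, S1, S2


class _CoxData:
    """Pre-sorted structures reused across Newton iterations."""

    def __init__(self, X, time, event, subcohort, cluster, policy: RiskSetPolicy):
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n, p = X.shape
        if event.sum() < 1:
            raise ValueError("no events in the data")
        sds = X.std(axis=0)
        if (sds == 0).any():
            raise ValueError(f"constant covariate: {np.argwhere(sds == 0).ravel()}")
        self.sds = sds
        if subcohort is None:
            subcohort = np.ones(n, dtype=int)
        subcohort = np.asarray(subcohort, dtype=int)
        invalid = (subcohort == 0) & (event == 0)
        if invalid.any():
            raise ValueError(
                "non-subcohort non-cases present; they carry no case-cohort risk time"
            )
        self.X, self.time, self.event = X, time, event
        self.A = subcohort == 1
        self.B = ~self.A  # non-subcohort cases
        self.cluster = np.arange(n) if cluster is None else np.asarray(cluster)
        self.policy = policy
        # at-risk weight multipliers (Barlow): subcohort person-time
        # up-weighted by 1/alpha; a subcohort case still counts weight 1 in
        # the tied-death correction term by convention.
        self.risk_w = np.ones(n)
        if policy.variant == "barlow":
            self.risk_w[self.A] = 1.0 / policy.sampling_fraction
        # distinct event times
        te = time[event == 1]
        self.ut, inv = np.unique(te, return_inverse=True)
        self.d = np.bincount(inv, minlength=len(self.ut)).astype(float)
        # per-event k index and within-tie position
        ev_idx = np.flatnonzero(event == 1)
        order = np.lexsort((ev_idx, inv))
        self.ev_rows = ev_idx[order]          # event rows sorted by time
        self.ev_k = inv[order]                # distinct-time index per event
        starts = np.concatenate([[0], np.cumsum(self.d)[:-1]])
        self.ev_l = np.arange(len(self.ev_rows)) - starts[self.ev_k]
        # B rows are all events; map each to its distinct-time slot
        b_rows = np.flatnonzero(self.B)
        self.b_rows = b_rows
        self.k_B = np.searchsorted(self.ut, time[b_rows])
        self.n, self.p = n, p

    def quantities(self, beta):
        """Log-likelihood, gradient, information at ``beta``."""
        X, time, event = self.X, self.time, self.event
        lp = X @ beta
        shift = lp.max()  # log-sum-exp guard; cancels in ratios
        w = np.exp(lp - shift) * self.risk_w
        A, B = self.A, self.b_rows
        S0, S1, S2 = _risk_sums(
            self.ut, self.p,
            time[A], w[A], X[A],
            self.k_B, w[B], X[B],
        )
        # tied-death sums use the same (possibly Barlow-weighted) w as the
        # risk set, so Breslow == Efron whenever d == 1
        ev = self.ev_rows
        V0 = np.bincount(self.ev_k, weights=w[ev], minlength=len(self.ut))
        V1 = np.zeros_like(S1)
        V2 = np.zeros_like(S2)
        wx_ev = w[ev][:, None] * X[ev]
        np.add.at(V1, self.ev_k, wx_ev)
        np.add.at(V2, self.ev_k, wx_ev[:, :, None] * X[ev][:, None, :])
        if self.policy.ties == "efron":
            f = self.ev_l / self.d[self.ev_k]
        else:
            f = np.zeros(len(ev))
        S0e = S0[self.ev_k] - f * V0[self.ev_k]
        S1e = S1[self.ev_k] - f[:, None] * V1[self.ev_k]
        S2e = S2[self.ev_k] - f[:, None, None] * V2[self.ev_k]
        with np.errstate(divide="ignore", invalid="ignore"):
            # S0e underflow in a wild Newton step gives -inf loglik, which
            # the step-halving in the caller rejects
            xbar = S1e / S0e[:, None]
            loglik = float(np.sum(X[ev] @ beta) - np.sum(np.log(S0e) + shift))
            grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
            info = (S2e / S0e[:, None, None]).sum(axis=0) - np.einsum(
                "ki,kj->ij", xbar, xbar
            )
        self._last = dict(w=w, S0e=S0e, S1e=S1e, xbar=xbar)
        return loglik, grad, info


def _newton(data: _CoxData, tol=1e-9, max_iter=50):
    beta = np.zeros(data.p)
    ll, grad, info = data.quantities(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving
        new_beta = beta + step
        new_ll, new_grad, new_info = data.quantities(new_beta)
        halves = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halves < 25:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_info = data.quantities(new_beta)
            halves += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < tol or np.max(np.abs(step)) < 1e-12:
            converged = True
            break
    if np.max(np.abs(beta) * data.sds) > 10:
        converged = False  # monotone likelihood / separation
    return beta, ll, grad, info, it, converged


def _score_residuals(data: _CoxData, beta):
    """Per-row score residuals for the clustered sandwich.

    Uses per-distinct-time hazard increments (summed over the tied deaths'
    Efron-adjusted denominators); exact for untied event times.
    """
    X, time = data.X, data.time
    last = data._last
    w, S0e, S1e = last["w"], last["S0e"], last["S1e"]
    K = len(data.ut)
    p = data.p
    # increments per distinct time
    h0 = np.bincount(data.ev_k, weights=1.0 / S0e, minlength=K)
    h1 = np.zeros((K, p))
    np.add.at(h1, data.ev_k, S1e / (S0e**2)[:, None])
    xbar_mean = np.zeros((K, p))
    np.add.at(xbar_mean, data.ev_k, S1e / S0e[:, None])
    xbar_mean /= data.d[:, None]
    H0 = np.cumsum(h0)
    H1 = np.cumsum(h1, axis=0)
    U = np.zeros((data.n, p))
    # death terms
    ev = data.ev_rows
    U[ev] += X[ev] - xbar_mean[data.ev_k]
    # at-risk integral: subcohort rows accumulate up to their stop time
    A = np.flatnonzero(data.A)
    kA = np.searchsorted(data.ut, time[A], side="right") - 1
    inA = kA >= 0
    Ain = A[inA]
    kAin = kA[inA]
    U[Ain] -= w[Ain, None] * (X[Ain] * H0[kAin][:, None] - H1[kAin])
    # case-only rows are at risk only at their own failure time
    Bc = data.b_rows
    if len(Bc):
        kB = data.k_B
        U[Bc] -= w[Bc, None] * (X[Bc] * h0[kB][:, None] - h1[kB])
    return U


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_years",
    event_col: str = "event",
    id_col: str = "id",
    subcohort_col: str | None = "subcohort",
    policy: RiskSetPolicy | None = None,
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a (case-cohort) Cox model.

    Parameters
    ----------
    df
        Analysis rows.  With ``subcohort_col`` set, rows must be subcohort
        members or cases (Prentice risk sets); pass ``subcohort_col=None``
        for an ordinary full-cohort fit.
    covariates
        Numeric design columns (categorical variables must already be
        dummy-coded; see :func:`pathprs.associations.build_design`).

    Raises
    ------
    ValueError
        On constant covariates, absent events, or invalid rows.
    ConvergenceError
        On a singular information matrix.
    """
    policy = policy or RiskSetPolicy()
    X = df[covariates].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in covariates; complete-case filter first")
    for j, name in enumerate(covariates):
        if X[:, j].std() == 0:
            raise ValueError(f"constant covariate: '{name}'")
    sub = None
    if subcohort_col is not None and subcohort_col in df.columns:
        sub = df[subcohort_col].to_numpy(dtype=int)
    cluster = df[id_col].to_numpy() if id_col in df.columns else None
    data = _CoxData(
        X,
        df[duration_col].to_numpy(dtype=float),
        df[event_col].to_numpy(dtype=int),
        sub,
        cluster,
        policy,
    )
    beta, ll, grad, info, it, converged = _newton(data, tol=tol, max_iter=max_iter)
    cov_model = np.linalg.inv(info)
    U = _score_residuals(data, beta)
    # collapse residuals within cluster (participant id)
    _, inv = np.unique(data.cluster, return_inverse=True)
    G = np.zeros((inv.max() + 1, data.p))
    np.add.at(G, inv, U)
    cov_robust = cov_model @ (G.T @ G) @ cov_model
    cov_robust = (cov_robust + cov_robust.T) / 2  # enforce exact symmetry
    fit = CoxFit(
        names=list(covariates),
        params=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        loglik=ll,
        n=data.n,
        n_events=int(data.event.sum()),
        iterations=it,
        converged=bool(converged),
        policy=policy,
    )
    fit._diag = dict(data=data, beta=beta)
    return fit


def wald_joint_test(fit: CoxFit, names_or_indices) -> tuple[float, int, float]:
    """Joint Wald test b' V^-1 b on a coefficient subset with robust V.

    Returns ``(chi2, df, p)``.
    """
    idx = []
    for item in names_or_indices:
        idx.append(fit.names.index(item) if isinstance(item, str) else int(item))
    idx = np.asarray(idx)
    b = fit.params[idx]
    V = fit.cov_robust[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular robust covariance submatrix: {exc}") from exc
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def ph_check(fit: CoxFit) -> pd.DataFrame:
    """Proportional-hazards diagnostic from scaled Schoenfeld residuals.

    For each covariate, Pearson correlation of the scaled residuals with
    event time and a t-test p-value.  Needs >= 3 events; otherwise the
    result is flagged undefined (NaN correlation/p, ``defined=False``).
    """
    data: _CoxData = fit._diag["data"]
    m = len(data.ev_rows)
    names = fit.names
    if m < 3:
        return pd.DataFrame(
            {"corr": np.nan, "p": np.nan, "defined": False}, index=names
        )
    # recompute at the solution to populate caches
    data.quantities(fit.params)
    xbar = data._last["xbar"]
    s = data.X[data.ev_rows] - xbar  # Schoenfeld residuals per death
    scaled = m * s @ fit.cov_model + fit.params  # cox.zph-style scaling
    t = data.time[data.ev_rows]
    out = []
    for j in range(len(names)):
        r = np.corrcoef(t, scaled[:, j])[0, 1]
        tt = r * np.sqrt((m - 2) / max(1 - r**2, 1e-15))
        p = 2 * stats.t.sf(abs(tt), m - 2)
        out.append((r, p, True))
    return pd.DataFrame(out, columns=["corr", "p", "defined"], index=names)
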