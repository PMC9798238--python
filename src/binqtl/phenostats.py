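"""Mixed-model BLUEs, REML variance components and entry-mean heritability.

Phenotype records are one row per line x environment x replicate. Two model
fits are used, mirroring standard multi-environment trial practice:

* the BLUE model treats lines as fixed and replicate blocks (nested in
  environment), environments and line-by-environment deviations as random;
  the fixed line estimates are the adjusted line means used for QTL mapping;
* the variance-component model treats lines as random (with genotype x year,
  genotype x location and genotype x year x location interactions when the
  environments decompose into year/location factors) and feeds the
  entry-mean broad-sense heritability

      H² = σG² / (σG² + σGY²/Y + σGL²/L + σGLY²/(Y·L) + σE²/(Y·L·R)).

REML is computed by EM iteration on Henderson's mixed-model equations with
Aitken acceleration; negative component iterates are truncated at (a tiny
positive floor above) zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the last iterate in ``components``."""

    def __init__(self, message: str, components: dict):
        super().__init__(message)
        self.components = components


@dataclass
class REMLFit:
    beta: np.ndarray
    beta_se: np.ndarray
    sigma2: dict[str, float]
    sigma2_e: float
    n_iter: int
    n_obs: int


def reml_em(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 2000,
    accelerate: bool = True,
) -> REMLFit:
    """EM-REML for y = Xβ + Σ Z_k u_k + e with independent random factors.

    Converged when every variance component changes by less than ``tol``
    relative to its value between successive iterations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = list(Zs)
    if not names:  # fixed-effects-only limit: ordinary least squares
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - p
        s2e = float(resid @ resid / dof) if dof > 0 else 0.0
        xtx_inv = np.linalg.pinv(X.T @ X)
        return REMLFit(beta, np.sqrt(np.clip(s2e * np.diag(xtx_inv), 0, None)),
                       {}, s2e, 0, n)

    Zmats = [np.asarray(Zs[k], dtype=float) for k in names]
    qs = [Z.shape[1] for Z in Zmats]
    W = np.hstack([X] + Zmats)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    offsets = np.cumsum([p] + qs)  # offsets[k+1] is the end of random block k
    blocks = [(int(offsets[k + 1] - qs[k]), int(offsets[k + 1])) for k in range(len(qs))]

    vary = max(float(np.var(y)), 1e-12)
    floor = 1e-12 * vary
    s2 = np.full(len(names), vary / (len(names) + 1))
    s2e = vary / 2.0
    history: list[np.ndarray] = []

    q_total = int(sum(qs))

    def _factor(s2, s2e):
        M = WtW.copy()
        for (lo, hi), sk in zip(blocks, s2):
            M[range(lo, hi), range(lo, hi)] += s2e / sk
        L = sla.cholesky(M, lower=True, check_finite=False)
        theta = sla.cho_solve((L, True), Wty, check_finite=False)
        return L, theta

    def _neg2_loglik(s2, s2e, L, theta) -> float:
        # restricted -2 log-likelihood (up to a constant) via the MME
        # identity log|V| + log|X'V^-1 X| = (n-p-q) log s2e + sum qk log sk
        # + log|M|, with log|M| from the Cholesky diagonal
        logdet_m = 2.0 * float(np.log(np.diag(L)).sum())
        ypy = (yty - float(theta @ Wty)) / s2e
        return (
            (n - p - q_total) * np.log(s2e)
            + float(np.dot(qs, np.log(s2)))
            + logdet_m
            + ypy
        )

    def _em_step(s2, s2e):
        # Block traces of the MME inverse come from column norms of L^-1
        # (cheaper than a full inverse)
        try:
            L, theta = _factor(s2, s2e)
            Linv = sla.lapack.dtrtri(L, lower=1)[0]
            inv_diag = np.einsum("ij,ij->j", Linv, Linv)
            n2ll = _neg2_loglik(s2, s2e, L, theta)
        except np.linalg.LinAlgError:
            M = WtW.copy()
            for (lo, hi), sk in zip(blocks, s2):
                M[range(lo, hi), range(lo, hi)] += s2e / sk
            Cinv = np.linalg.pinv(M)
            theta = Cinv @ Wty
            inv_diag = np.diag(Cinv)
            n2ll = np.inf
        new = np.empty_like(s2)
        for i, (lo, hi) in enumerate(blocks):
            u = theta[lo:hi]
            new[i] = (u @ u + s2e * inv_diag[lo:hi].sum()) / qs[i]
        s2e_new = (yty - float(theta @ Wty)) / (n - p)
        return np.maximum(new, floor), max(s2e_new, floor), theta, inv_diag, n2ll

    pin = 1e-8 * vary  # components below this are at the zero boundary
    pinned = np.zeros(len(names), dtype=bool)
    low_count = np.zeros(len(names), dtype=int)
    prev_n2ll = np.inf
    stalled = 0
    for it in range(1, max_iter + 1):
        s2_new, s2e_new, _, _, n2ll = _em_step(s2, s2e)
        s2_new[pinned] = floor
        vec_old = np.concatenate([s2, [s2e]])
        vec_new = np.concatenate([s2_new, [s2e_new]])
        active = np.concatenate([~pinned, [True]])
        rel = np.max(
            np.abs(vec_new - vec_old)[active] / np.maximum(vec_old[active], floor)
        )
        s2, s2e = s2_new, s2e_new
        history.append(vec_new)
        if rel < tol:
            break
        # secondary stop: EM increases the restricted likelihood monotonely,
        # so a persistent plateau means the fit is converged even if a tiny
        # near-boundary component is still drifting at a geometric rate
        stalled = stalled + 1 if prev_n2ll - n2ll < 1e-10 * (1 + abs(n2ll)) else 0
        prev_n2ll = n2ll
        if stalled >= 10:
            break
        # a component stuck near zero is fixed at the boundary
        low_count = np.where(s2 < pin, low_count + 1, 0)
        newly = (~pinned) & (low_count >= 3)
        if newly.any():
            pinned |= newly
            s2[pinned] = floor
            history.clear()
            continue
        # Aitken extrapolation over three consecutive plain EM iterates,
        # accepted only when it does not decrease the restricted likelihood
        # relative to the current iterate (EM itself is monotone, so the
        # safeguarded sequence is monotone and cannot cycle)
        if accelerate and len(history) >= 3:
            v0, v1, v2 = history[-3], history[-2], history[-1]
            denom = (v2 - v1) - (v1 - v0)
            safe = np.abs(denom) > 1e-300
            acc = v2.copy()
            acc[safe] = v2[safe] - (v2[safe] - v1[safe]) ** 2 / denom[safe]
            good = np.isfinite(acc) & (acc > 0) & (acc < 5.0 * v2)
            acc[~good] = v2[~good]
            acc_s2 = np.maximum(acc[:-1], floor)
            acc_s2[pinned] = floor
            acc_s2e = max(float(acc[-1]), floor)
            try:
                n2ll_acc = _neg2_loglik(acc_s2, acc_s2e, *_factor(acc_s2, acc_s2e))
                n2ll_cur = _neg2_loglik(s2, s2e, *_factor(s2, s2e))
            except np.linalg.LinAlgError:
                n2ll_acc, n2ll_cur = np.inf, -np.inf
            if n2ll_acc <= n2ll_cur:
                s2, s2e = acc_s2, acc_s2e
                history.clear()
    else:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} EM iterations",
            components=dict(zip(names + ["residual"], np.concatenate([s2, [s2e]]))),
        )
    # one final solve at the converged components for estimates and SEs
    _, _, theta, inv_diag, _ = _em_step(s2, s2e)
    beta = theta[:p]
    beta_se = np.sqrt(np.clip(s2e * inv_diag[:p], 0.0, None))
    s2_report = np.where(pinned | (s2 <= 2.0 * floor), 0.0, s2)
    return REMLFit(
        beta=beta,
        beta_se=beta_se,
        sigma2=dict(zip(names, (float(v) for v in s2_report))),
        sigma2_e=float(s2e),
        n_iter=it,
        n_obs=n,
    )


# --------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Genetic and interaction variances plus the trial design counts."""

    var_g: float
    var_gy: float
    var_gl: float
    var_gly: float
    var_e: float
    n_years: int
    n_locations: int
    n_reps: int
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("var_g", "var_gy", "var_gl", "var_gly", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_years, self.n_locations, self.n_reps) < 1:
            raise ValueError("design counts must be >= 1")


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability across environments."""
    y, l, r = vc.n_years, vc.n_locations, vc.n_reps
    denom = (
        vc.var_g
        + vc.var_gy / y
        + vc.var_gl / l
        + vc.var_gly / (l * y)
        + vc.var_e / (l * y * r)
    )
    if denom <= 0:
        raise ValueError("all variance components are zero; H² undefined")
    return vc.var_g / denom


def _dummies(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values.astype(str)).to_numpy(dtype=float)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"line", "env", "rep", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"phenotype records missing columns: {sorted(missing)}")
    if records.duplicated(["line", "env", "rep"]).any():
        raise ValueError("duplicate (line, env, rep) records")
    if not np.all(np.isfinite(records["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite phenotype values")
    return records.reset_index(drop=True)


def fit_blues(
    records: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[pd.DataFrame, REMLFit]:
    """Adjusted line means: fixed intercept+line, random rep(env), env, line:env.

    Returns a BLUE table (line, blue, se) and the underlying fit. With a
    single environment the env and line:env components are dropped (fixed at
    zero).
    """
    rec = _validate_records(records)
    lines = sorted(rec["line"].astype(str).unique())
    X = pd.get_dummies(rec["line"].astype(str))[lines].to_numpy(dtype=float)
    n_env = rec["env"].nunique()
    Zs: dict[str, np.ndarray] = {}
    rep_in_env = rec["env"].astype(str) + ":" + rec["rep"].astype(str)
    if rep_in_env.nunique() > n_env:
        Zs["rep"] = _dummies(rep_in_env)
    if n_env > 1:
        Zs["env"] = _dummies(rec["env"])
        Zs["line:env"] = _dummies(rec["line"].astype(str) + ":" + rec["env"].astype(str))
    fit = reml_em(rec["value"].to_numpy(dtype=float), X, Zs, tol=tol, max_iter=max_iter)
    table = pd.DataFrame({"line": lines, "blue": fit.beta, "se": fit.beta_se})
    return table, fit


def fit_variance_components(
    records: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> VarianceComponents:
    """Random-line REML fit feeding the H² formula.

    When year and location columns are present, environments decompose into
    year x location cells: genotype x year, genotype x location and genotype
    x cell variances are fitted (terms whose factor has a single level are
    fixed at zero). Without the decomposition, environments are treated as
    locations of a single year and the G x E variance is reported as σGL².
    """
    rec = _validate_records(records)
    has_yl = {"year", "location"} <= set(records.columns)
    line = rec["line"].astype(str)
    env = rec["env"].astype(str)
    n_env = env.nunique()
    reps_per_env = rec.groupby("env")["rep"].nunique()
    n_reps = int(reps_per_env.min())

    Zs: dict[str, np.ndarray] = {"line": _dummies(line)}
    rep_in_env = env + ":" + rec["rep"].astype(str)
    if rep_in_env.nunique() > n_env:
        Zs["rep"] = _dummies(rep_in_env)

    if has_yl:
        year = rec["year"].astype(str)
        loc = rec["location"].astype(str)
        n_years, n_locs = year.nunique(), loc.nunique()
        X = _dummies(year + ":" + loc)  # fixed environment-cell means
        if n_years > 1:
            Zs["line:year"] = _dummies(line + ":" + year)
        if n_locs > 1:
            Zs["line:loc"] = _dummies(line + ":" + loc)
        if n_years > 1 and n_locs > 1 and n_env > max(n_years, n_locs):
            Zs["line:env"] = _dummies(line + ":" + env)
    else:
        n_years, n_locs = 1, n_env
        X = _dummies(env)
        if n_env > 1:
            Zs["line:loc"] = _dummies(line + ":" + env)

    fit = reml_em(rec["value"].to_numpy(dtype=float), X, Zs, tol=tol, max_iter=max_iter)
    s2 = fit.sigma2
    return VarianceComponents(
        var_g=s2.get("line", 0.0),
        var_gy=s2.get("line:year", 0.0),
        var_gl=s2.get("line:loc", 0.0),
        var_gly=s2.get("line:env", 0.0),
        var_e=fit.sigma2_e,
        n_years=n_years,
        n_locations=n_locs,
        n_reps=max(n_reps, 1),
        extras={k: v for k, v in s2.items() if k in ("rep",)},
    )


def fit_mixed_model(
    records: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[pd.DataFrame, VarianceComponents]:
    """BLUE table plus variance components (two REML fits; see module docs)."""
    rec = _validate_records(records)
    if rec["line"].nunique() < 2:
        raise ValueError("need at least 2 lines")
    blues, _ = fit_blues(rec, tol=tol, max_iter=max_iter)
    vc = fit_variance_components(rec, tol=tol, max_iter=max_iter)
    return blues, vc


def env_correlations(records: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlations of per-line environment means, pairwise-complete.

    Environment pairs sharing fewer than ``min_shared`` lines are NaN.
    """
    rec = _validate_records(records)
    if rec["env"].nunique() < 2:
        raise ValueError("need at least 2 environments")
    means = rec.groupby(["line", "env"])["value"].mean().unstack("env")
    return means.corr(method="pearson", min_periods=min_shared)


def reml_loglik(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    sigma2: dict[str, float],
    sigma2_e: float,
) -> float:
    """Restricted log-likelihood at given components (dense V; small data)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    V = sigma2_e * np.eye(n)
    for k, Z in Zs.items():
        Z = np.asarray(Z, dtype=float)
        V += sigma2[k] * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtViX, X.T @ Vinv @ y)
    resid = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_v + ld_x + resid @ Vinv @ resid + (n - p) * np.log(2 * np.pi))
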