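"""Gaussian additive mixed models for daily rank scores.

The rank stage models a male's daily (z-scored) cardinal Elo score as a
sum of penalized smooth functions of age and personality:

* fixed effects are tensor-product interaction (``ti``) smooths built
  from cubic regression splines with *shrinkage* penalties, so a term's
  effective degrees of freedom (edf) can be driven to zero and the term
  removed from the model entirely;
* random effects are ridge-penalized parametric smooths — per-male
  intercepts and per-male slopes in age and each trait (and optionally a
  per-date intercept);
* smoothing parameters are chosen by restricted maximum likelihood
  (REML), and nested models are compared by chi-square tests on twice
  the difference in the minimized REML criterion.

The engine is self-contained (numpy/scipy linear algebra).  The cubic
regression spline uses the value-at-knots parameterisation with natural
boundary conditions and the integrated-squared-second-derivative
penalty; shrinkage is double-penalty style — each smooth's penalty null
space (the linear part a wiggliness penalty cannot touch) gets its own
ridge with a separate smoothing parameter, so REML can retain a purely
linear effect at edf 1 or remove a term entirely at edf 0.  Smooth
terms are centred (sum-to-zero over the training rows), which is why a
5-knot main-effect smooth carries 4 reference df and a 5 x 5 tensor
interaction 16.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "CubicRegressionSpline",
    "SmoothTerm",
    "TensorTerm",
    "RandomInterceptTerm",
    "RandomSlopeTerm",
    "GammSpec",
    "GammFit",
    "CvResult",
    "standard_spec",
    "build_rank_table",
    "fit_gamm",
    "reml_compare",
    "cross_validate",
    "vif",
]

TRAITS = ["dominance", "extraversion", "conscientiousness",
          "agreeableness", "neuroticism", "openness"]

# ---------------------------------------------------------------------------
# cubic regression spline basis


class CubicRegressionSpline:
    """Natural cubic spline in the value-at-knots parameterisation.

    Coefficients are the function values at the ``k`` knots; second
    derivatives at the knots are the linear map ``m = F beta`` implied by
    spline continuity with natural boundary conditions, and the wiggliness
    penalty is ``S = D' B^{-1} D`` (integrated squared second derivative).
    Evaluation outside the knot range clamps to the boundary value by
    default (safe under out-of-sample prediction, where linear
    extrapolation of tensor-product terms can run away); pass
    ``extrapolate="linear"`` for genuine linear extrapolation.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 3:
            raise ValueError("need at least 3 strictly increasing knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        D = np.zeros((k - 2, k))
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        Binv_D = linalg.solve(B, D, assume_a="pos")
        self.F = np.vstack([np.zeros(k), Binv_D, np.zeros(k)])  # k x k
        self.S = D.T @ Binv_D  # wiggliness penalty, rank k-2
        self._h = h

    @classmethod
    def from_data(cls, x: np.ndarray, k: int = 5) -> "CubicRegressionSpline":
        """Knots at evenly spaced quantiles of the unique covariate values."""
        ux = np.unique(np.asarray(x, dtype=float))
        k = min(k, len(ux))
        if k < 3:
            raise ValueError(
                f"covariate has {len(ux)} unique values; need >= 3 knots")
        knots = np.quantile(ux, np.linspace(0.0, 1.0, k))
        knots = np.unique(knots)
        return cls(knots)

    def design(self, x: np.ndarray, extrapolate: str = "clamp") -> np.ndarray:
        """Model matrix rows mapping knot values to f(x)."""
        x = np.asarray(x, dtype=float)
        kn, F = self.knots, self.F
        k = len(kn)
        lo, hi = kn[0], kn[-1]
        xc = np.clip(x, lo, hi)
        j = np.clip(np.searchsorted(kn, xc, side="right") - 1, 0, k - 2)
        h = self._h[j]
        xr = kn[j + 1] - xc
        xl = xc - kn[j]
        am, ap = xr / h, xl / h
        cm = (xr ** 3 / h - h * xr) / 6.0
        cp = (xl ** 3 / h - h * xl) / 6.0
        X = np.zeros((len(x), k))
        rows = np.arange(len(x))
        np.add.at(X, (rows, j), am)
        np.add.at(X, (rows, j + 1), ap)
        X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
        if extrapolate == "clamp":
            return X
        # linear extrapolation beyond the boundary knots
        out_lo = x < lo
        out_hi = x > hi
        for mask, x0, jj in ((out_lo, lo, 0), (out_hi, hi, k - 2)):
            if not mask.any():
                continue
            hh = self._h[jj]
            d_row = np.zeros(k)
            d_row[jj] -= 1.0 / hh
            d_row[jj + 1] += 1.0 / hh
            sgn = -1.0 if jj == 0 else 1.0
            # derivative of the cubic pieces at the boundary knot
            d_row += sgn * (hh / 3.0) * F[jj if jj == 0 else jj + 1]
            d_row += sgn * (hh / 6.0) * F[jj + 1 if jj == 0 else jj]
            X[mask] += (x[mask] - x0)[:, None] * d_row[None, :]
        return X


def _null_penalty(*S_list: np.ndarray) -> np.ndarray | None:
    """Ridge penalty on the joint null space of the given penalties.

    Shrinkage is implemented double-penalty style: the wiggliness
    penalties keep their own smoothing parameters, and the directions
    they cannot touch (e.g. the linear part of a cubic spline) receive a
    separate ridge with its own parameter.  A purely linear effect can
    then reach edf 1 (wiggliness fully penalized, null space free) and a
    null effect edf 0 (both penalized away).
    """
    total = sum(S_list)
    vals, vecs = linalg.eigh(total)
    tol = max(vals.max(), 0.0) * 1e-8
    null = vecs[:, vals <= tol]
    if null.shape[1] == 0:
        return None
    return null @ null.T


def _center_basis(X: np.ndarray, S_list: list[np.ndarray]
                  ) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Apply the sum-to-zero identifiability constraint via a null-space map."""
    c = X.mean(axis=0)
    Z = linalg.null_space(c[None, :])
    return X @ Z, [Z.T @ S @ Z for S in S_list], Z


# ---------------------------------------------------------------------------
# model terms


class SmoothTerm:
    """Centred 1-D shrinkage smooth of one covariate (``ti``-style main)."""

    def __init__(self, var: str, k: int = 5):
        self.var = var
        self.k = k
        self.name = f"ti({var})"
        self.penalized = True

    def build(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.var].to_numpy(float)
        self.spline = CubicRegressionSpline.from_data(x, self.k)
        X = self.spline.design(x)
        Xc, Ss, self.Z = _center_basis(X, [self.spline.S])
        null = _null_penalty(*Ss)
        self.penalties = Ss + ([null] if null is not None else [])
        self.ref_df = Xc.shape[1]
        return Xc

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.spline.design(df[self.var].to_numpy(float)) @ self.Z


class TensorTerm:
    """Tensor-product interaction smooth of two covariates (``ti``).

    Marginal bases are centred shrinkage cubic regression splines; the
    tensor design is their row-wise Kronecker product, with one penalty
    (and smoothing parameter) per margin.
    """

    def __init__(self, var1: str, var2: str, k: int = 5):
        self.var1, self.var2, self.k = var1, var2, k
        self.name = f"ti({var1},{var2})"
        self.penalized = True

    def _marginal(self, df, var):
        x = df[var].to_numpy(float)
        spline = CubicRegressionSpline.from_data(x, self.k)
        X = spline.design(x)
        Xc, Ss, Z = _center_basis(X, [spline.S])
        return spline, Z, Xc, Ss[0]

    def build(self, df: pd.DataFrame) -> np.ndarray:
        self.sp1, self.Z1, X1, S1 = self._marginal(df, self.var1)
        self.sp2, self.Z2, X2, S2 = self._marginal(df, self.var2)
        d1, d2 = X1.shape[1], X2.shape[1]
        X = (X1[:, :, None] * X2[:, None, :]).reshape(len(df), d1 * d2)
        pens = [np.kron(S1, np.eye(d2)), np.kron(np.eye(d1), S2)]
        null = _null_penalty(*pens)
        self.penalties = pens + ([null] if null is not None else [])
        self.ref_df = d1 * d2
        return X

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X1 = self.sp1.design(df[self.var1].to_numpy(float)) @ self.Z1
        X2 = self.sp2.design(df[self.var2].to_numpy(float)) @ self.Z2
        return (X1[:, :, None] * X2[:, None, :]).reshape(len(df), -1)


class RandomInterceptTerm:
    """Ridge-penalized per-level intercepts, ``s(group, bs='re')``."""

    def __init__(self, group: str):
        self.group = group
        self.name = f"s({group})"
        self.penalized = True

    def build(self, df: pd.DataFrame) -> np.ndarray:
        self.levels = pd.Index(sorted(df[self.group].unique()))
        self.penalties = [np.eye(len(self.levels))]
        self.ref_df = len(self.levels)
        return self._dummies(df)

    def _dummies(self, df: pd.DataFrame) -> np.ndarray:
        codes = self.levels.get_indexer(df[self.group])
        X = np.zeros((len(df), len(self.levels)))
        seen = codes >= 0  # unseen levels predict at the population level
        X[np.where(seen)[0], codes[seen]] = 1.0
        return X

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self._dummies(df)


class RandomSlopeTerm(RandomInterceptTerm):
    """Ridge-penalized per-level slopes in a covariate."""

    def __init__(self, group: str, var: str):
        super().__init__(group)
        self.var = var
        self.name = f"s({group},{var})"

    def _dummies(self, df: pd.DataFrame) -> np.ndarray:
        return super()._dummies(df) * df[self.var].to_numpy(float)[:, None]


# ---------------------------------------------------------------------------
# model specification


@dataclasses.dataclass
class GammSpec:
    """One model of the rank suite.

    ``traits`` enter as centred main-effect smooths plus age x trait
    tensor interactions; every model carries a per-male random intercept
    and random slopes in age and each included trait.  ``date_re`` adds a
    per-date random intercept (the autocorrelation check).
    """

    index: int
    traits: tuple[str, ...] = ()
    date_re: bool = False
    k: int = 5
    group: str = "male_id"
    age_var: str = "age_z"

    def terms(self) -> list:
        t: list = [SmoothTerm(self.age_var, self.k)]
        for trait in self.traits:
            t.append(SmoothTerm(f"{trait}_z", self.k))
        for trait in self.traits:
            t.append(TensorTerm(self.age_var, f"{trait}_z", self.k))
        t.append(RandomInterceptTerm(self.group))
        t.append(RandomSlopeTerm(self.group, self.age_var))
        for trait in self.traits:
            t.append(RandomSlopeTerm(self.group, f"{trait}_z"))
        if self.date_re:
            t.append(RandomInterceptTerm("date"))
        return t


def standard_spec(index: int, k: int = 5) -> GammSpec:
    """The six-model suite: 1 age-only; 2 +Dominance; 3 +Conscientiousness;
    4 +both; 5 all six traits; 6 model 5 plus a date random effect."""
    table = {
        1: (),
        2: ("dominance",),
        3: ("conscientiousness",),
        4: ("dominance", "conscientiousness"),
        5: tuple(TRAITS),
        6: tuple(TRAITS),
    }
    if index not in table:
        raise ValueError("model index must be in 1..6")
    return GammSpec(index=index, traits=table[index], date_re=(index == 6), k=k)


# ---------------------------------------------------------------------------
# fitting


@dataclasses.dataclass
class GammFit:
    spec: GammSpec
    terms: list
    slices: list[slice]
    beta: np.ndarray
    cov: np.ndarray
    lambdas: np.ndarray
    sigma2: float
    reml_score: float
    edf_by_term: pd.Series
    ref_df_by_term: pd.Series
    chi2_by_term: pd.Series
    p_by_term: pd.Series
    edf_total: float
    deviance: float
    deviance_explained: float
    adjusted_r2: float
    n_obs: int
    converged: bool
    outcome: str

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(df), 1))]
        cols += [t.predict(df) for t in self.terms]
        return np.hstack(cols) @ self.beta

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"edf": self.edf_by_term,
                             "ref_df": self.ref_df_by_term,
                             "chi2": self.chi2_by_term,
                             "p": self.p_by_term})


def _assemble(table: pd.DataFrame, spec, outcome: str):
    terms = spec.terms() if hasattr(spec, "terms") else list(spec)
    cols = [np.ones((len(table), 1))]
    slices, pen_blocks = [], []
    p = 1
    for t in terms:
        X_t = t.build(table)
        cols.append(X_t)
        slices.append(slice(p, p + X_t.shape[1]))
        for S in t.penalties:
            # normalize so log-smoothing-parameters share a common scale
            pen_blocks.append((slices[-1], S / np.linalg.norm(S)))
        p += X_t.shape[1]
    X = np.hstack(cols)
    y = table[outcome].to_numpy(float)
    return terms, X, y, slices, pen_blocks


def _reml_pieces(XtX, Xty, yty, n, pen_blocks, rho):
    p = XtX.shape[0]
    S_lam = np.zeros((p, p))
    logdet_S = 0.0
    for (sl, S), r in zip(pen_blocks, rho, strict=True):
        S_lam[sl, sl] += math.exp(r) * S
    # pseudo log-determinant over the penalized subspace, block by block
    seen: dict[tuple[int, int], list] = {}
    for (sl, S), r in zip(pen_blocks, rho):
        seen.setdefault((sl.start, sl.stop), []).append((math.exp(r), S))
    m_p = p
    for (a, b), parts in seen.items():
        block = sum(lam * S for lam, S in parts)
        sign, ld = np.linalg.slogdet(block)
        if sign <= 0:
            raise linalg.LinAlgError("singular penalty block")
        logdet_S += ld
        m_p -= b - a
    A = XtX + S_lam
    try:
        cA = linalg.cho_factor(A)
    except linalg.LinAlgError:
        cA = linalg.cho_factor(A + 1e-8 * np.eye(p) * np.trace(A) / p)
    beta = linalg.cho_solve(cA, Xty)
    logdet_A = 2.0 * np.sum(np.log(np.diag(cA[0])))
    rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
    dp = rss + beta @ S_lam @ beta
    nr = n - m_p
    sigma2 = max(dp / nr, 1e-300)
    score = 0.5 * nr * (1.0 + math.log(2.0 * math.pi * sigma2)) \
        + 0.5 * (logdet_A - logdet_S)
    return score, beta, cA, sigma2, rss, S_lam


def fit_gamm(table: pd.DataFrame, spec,
             outcome: str = "elo_z", maxiter: int = 200,
             log_lambdas: np.ndarray | None = None) -> GammFit:
    """Fit one rank GAMM by penalized least squares with REML-selected
    smoothing parameters.

    ``spec`` is a :class:`GammSpec` or a bare sequence of term objects
    (an intercept is always included).  ``log_lambdas`` fixes the
    smoothing parameters (skipping REML selection) — used when refitting
    coefficients on data subsets during cross-validation.

    Deterministic given data and spec.  Non-convergence of the smoothing
    parameter search is flagged on the returned fit, which still carries
    the diagnostics at the best point found.
    """
    if table.empty:
        raise ValueError("empty modeling table")
    terms, X, y, slices, pen_blocks = _assemble(table, spec, outcome)
    n, p = X.shape
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    def score_fn(rho):
        try:
            return _reml_pieces(XtX, Xty, yty, n, pen_blocks, rho)[0]
        except linalg.LinAlgError:
            return np.inf

    if log_lambdas is not None:
        class res:  # fixed smoothing parameters, nothing to optimize
            x = np.asarray(log_lambdas, dtype=float)
            success = True
    else:
        rho0 = np.zeros(len(pen_blocks))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(score_fn, rho0, method="L-BFGS-B",
                                    bounds=[(-12.0, 25.0)] * len(pen_blocks),
                                    options={"maxiter": maxiter})
    score, beta, cA, sigma2, rss, S_lam = _reml_pieces(
        XtX, Xty, yty, n, pen_blocks, res.x)

    Ainv = linalg.cho_solve(cA, np.eye(p))
    Fmat = Ainv @ XtX
    edf_diag = np.diag(Fmat)
    cov = Ainv * sigma2

    names, edfs, refs, chi2s, pvals = [], [], [], [], []
    for t, sl in zip(terms, slices):
        names.append(t.name)
        edf_t = float(edf_diag[sl].sum())
        edfs.append(edf_t)
        refs.append(t.ref_df)
        b_t = beta[sl]
        V_t = cov[sl, sl]
        stat = float(b_t @ np.linalg.pinv(V_t, rcond=1e-10) @ b_t)
        chi2s.append(stat)
        if edf_t < 0.05:  # term shrunk out of the model: no evidence
            pvals.append(1.0)
        else:
            pvals.append(float(stats.chi2.sf(stat, edf_t)))
    edf_total = float(edf_diag.sum())
    tss = float(np.sum((y - y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss
    adj_r2 = 1.0 - (rss / max(n - edf_total, 1.0)) / (tss / (n - 1))
    return GammFit(spec=spec, terms=terms, slices=slices, beta=beta, cov=cov,
                   lambdas=np.exp(res.x), sigma2=sigma2,
                   reml_score=float(score),
                   edf_by_term=pd.Series(edfs, index=names),
                   ref_df_by_term=pd.Series(refs, index=names, dtype=float),
                   chi2_by_term=pd.Series(chi2s, index=names),
                   p_by_term=pd.Series(pvals, index=names),
                   edf_total=edf_total, deviance=float(rss),
                   deviance_explained=float(dev_expl),
                   adjusted_r2=float(adj_r2), n_obs=n,
                   converged=bool(res.success), outcome=outcome)


def reml_compare(fit_a: GammFit, fit_b: GammFit) -> dict[str, float]:
    """Chi-square test of twice the difference in minimized REML score
    between two nested fits on the same data."""
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("fits are not on the same data (different n)")
    stat = 2.0 * abs(fit_a.reml_score - fit_b.reml_score)
    df = abs(fit_a.edf_total - fit_b.edf_total)
    p = float(stats.chi2.sf(stat, max(df, 1e-8)))
    return {"chi2": float(stat), "df": float(df), "p": p}


# ---------------------------------------------------------------------------
# modeling table, cross-validation, collinearity


def build_rank_table(daily: pd.DataFrame, traits: pd.DataFrame,
                     roster: pd.DataFrame) -> pd.DataFrame:
    """One modeling row per male-day.

    Carries z-transformed age (over rows), z-transformed trait scores
    (over the male sample present in the table), and the z-transformed
    cardinal score as outcome ``elo_z``.  Males lacking trait scores are
    excluded with a warning.
    """
    births = roster.set_index("male_id")["birth_date"]
    df = daily.dropna(subset=["cardinal"]).copy()
    missing = sorted(set(df["male_id"]) - set(traits.index))
    if missing:
        warnings.warn(f"males without trait scores excluded: {missing}")
        df = df[~df["male_id"].isin(missing)]
    df["age"] = (df["date"].to_numpy() - df["male_id"].map(births).to_numpy()) \
        / np.timedelta64(1, "D") / 365.25
    df["age_z"] = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
    df["elo_z"] = (df["cardinal"] - df["cardinal"].mean()) \
        / df["cardinal"].std(ddof=1)
    male_traits = traits.loc[sorted(set(df["male_id"]))]
    for trait in TRAITS:
        z = (male_traits[trait] - male_traits[trait].mean()) \
            / male_traits[trait].std(ddof=1)
        df[f"{trait}_z"] = df["male_id"].map(z)
    return df.reset_index(drop=True)


@dataclasses.dataclass
class CvResult:
    scheme: str
    fold_mse: list[float]
    mean_mse: float
    seed: int | None
    fold_assignment: np.ndarray
    train_indices: list[np.ndarray] | None = None


def _stratified_folds(table: pd.DataFrame, n_folds: int, seed: int,
                      group: str = "male_id") -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold = np.empty(len(table), dtype=int)
    for _, grp in table.groupby(group, sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < n_folds:
            warnings.warn(f"male with {len(idx)} rows pooled across folds")
        perm = rng.permutation(idx)
        fold[perm] = (np.arange(len(idx)) + rng.integers(n_folds)) % n_folds
    return fold


def cross_validate(table: pd.DataFrame, spec: GammSpec, scheme: str,
                   seed: int | None = None, n_folds: int = 10,
                   outcome: str = "elo_z",
                   refit_smoothing: bool = False) -> CvResult:
    """Predictive mean squared error under two schemes.

    ``stratified``: each male's rows are split across ``n_folds`` folds at
    random (seeded); each fold is predicted from a fit on the rest.
    ``forward``: rows ordered by date are cut into ``n_folds`` sequential
    blocks; blocks ``1..m`` train a fit that predicts block ``m+1``, for
    ``m = 1..n_folds-1`` — every prediction uses only past data.

    By default the smoothing parameters are estimated once on the full
    table and held fixed while per-fold fits re-estimate coefficients
    only; re-selecting smoothness on small early folds, where age and
    male identity are heavily confounded, is unstable
    (``refit_smoothing=True`` restores full per-fold REML selection).
    """
    table = table.reset_index(drop=True)
    y = table[outcome].to_numpy(float)
    rho = None
    if not refit_smoothing:
        rho = np.log(fit_gamm(table, spec, outcome=outcome).lambdas)
    mses: list[float] = []
    train_idx_log: list[np.ndarray] = []
    if scheme == "stratified":
        if seed is None:
            raise ValueError("stratified scheme requires a seed")
        fold = _stratified_folds(table, n_folds, seed)
        for f in range(n_folds):
            test = fold == f
            fit = fit_gamm(table[~test], spec, outcome=outcome,
                           log_lambdas=rho)
            pred = fit.predict(table[test])
            mses.append(float(np.mean((y[test] - pred) ** 2)))
            train_idx_log.append(np.where(~test)[0])
    elif scheme == "forward":
        order = np.argsort(table["date"].to_numpy(), kind="stable")
        fold = np.empty(len(table), dtype=int)
        fold[order] = np.minimum(
            np.arange(len(table)) * n_folds // len(table), n_folds - 1)
        for m in range(1, n_folds):
            train = fold < m
            test = fold == m
            fit = fit_gamm(table[train], spec, outcome=outcome,
                           log_lambdas=rho)
            pred = fit.predict(table[test])
            mses.append(float(np.mean((y[test] - pred) ** 2)))
            train_idx_log.append(np.where(train)[0])
    else:
        raise ValueError("scheme must be 'stratified' or 'forward'")
    return CvResult(scheme=scheme, fold_mse=mses,
                    mean_mse=float(np.mean(mses)), seed=seed,
                    fold_assignment=fold, train_indices=train_idx_log)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each column regressed on the others."""
    X = design.to_numpy(float)
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least 2 columns")
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ coef
        tss = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
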