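"""Penalized-spline additive mixed model with nested random intercepts,
continuous-time AR(1) residual correlation, and per-group variance weights.

Model
-----
For a transformed response y and sample i,

    y_i = β₀ + Σ_f factor terms + Σ_c s_c(x_ci) + b_wb(i) + b_st(i) + ε_i

where each s_c is a cubic regression spline with a quadratic roughness
penalty, b_wb and b_st are water-body and station random intercepts
(expressed as ridge-penalized coefficients), and the residuals within a
station follow a continuous-time AR(1) process, corr(ε_i, ε_j) = φ^|t_i−t_j|,
with a variance multiplier per sea area.  Smoothing parameters, random
intercept precisions, φ and the variance multipliers are all estimated by
restricted marginal likelihood (REML): an inner quasi-Newton step over the
log smoothing parameters alternates with REML updates of φ and
moment-based updates of the variance weights until relative change falls
below tolerance.

Inference uses the Bayesian covariance of the penalized coefficients
(σ² (XᵀV⁻¹X + S_λ)⁻¹).  Smooth-term tests are Wald-type chi-square tests on
the fitted smooth with rank set by the rounded effective degrees of
freedom; factor terms use a joint Wald F-test.  Factor-level marginal
means are model predictions at reference covariate values with balanced
weights over the other factor, and all pairwise contrasts are adjusted
with the studentized-range (Tukey) distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_K = 6
ALPHA = 0.001


class GammError(ValueError):
    pass


# --------------------------------------------------------------------------
# cubic regression spline basis (value-at-knot parameterisation)


def _crs_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Penalty building blocks for a cubic regression spline on ``knots``.

    Returns (F, S): F maps coefficient values at knots to second
    derivatives at the interior knots, and S = DᵀB⁻¹D is the integrated
    squared second-derivative penalty.
    """
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = linalg.solve(B, D, assume_a="pos")
    S = D.T @ F
    return F, S


def crs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the cubic regression spline basis at ``x``.

    Coefficients are the spline's values at the knots.  Values outside the
    knot range are evaluated at the nearest boundary (flat extension);
    training knots span the data so this only affects prediction.
    """
    x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
    k = knots.size
    F, _ = _crs_matrices(knots)
    Ft = np.vstack([np.zeros(k), F, np.zeros(k)])  # second derivs incl. natural BCs
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    h = np.diff(knots)[j]
    lo, hi = knots[j], knots[j + 1]
    a_m = (hi - x) / h
    a_p = (x - lo) / h
    c_m = ((hi - x) ** 3 / h - h * (hi - x)) / 6.0
    c_p = ((x - lo) ** 3 / h - h * (x - lo)) / 6.0
    N = np.zeros((x.size, k))
    rows = np.arange(x.size)
    N[rows, j] += a_m
    N[rows, j + 1] += a_p
    N += c_m[:, None] * Ft[j] + c_p[:, None] * Ft[j + 1]
    return N


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    knots = np.unique(np.quantile(x, np.linspace(0, 1, k)))
    if knots.size < 4:
        raise GammError("covariate has too few distinct values for a spline basis")
    return knots


# --------------------------------------------------------------------------
# model specification and design


@dataclass(frozen=True)
class GAMMSpec:
    """Model structure: smooths, parametric factors, random intercepts,
    residual correlation and variance model."""

    smooths: tuple[str, ...] = ("Temp", "Sal", "Secchi", "E", "TP")
    k: int = DEFAULT_K
    factors: tuple[str, ...] = ("L", "Area")
    random: tuple[str, ...] = ("water_body", "station")
    ar1_group: Optional[str] = "station"
    ar1_time: Optional[str] = "date"
    variance_by: Optional[str] = "Area"
    alpha: float = ALPHA
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 4:
            raise GammError("spline basis dimension k must be ≥ 4")


def spec_from_file(path) -> "GAMMSpec":
    """Load a :class:`GAMMSpec` from a YAML or JSON mapping.

    Recognised keys mirror the dataclass fields (smooths, k, factors,
    random, ar1_group, ar1_time, variance_by, alpha, max_iter, tol);
    list values are converted to tuples.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise GammError(f"model config {path} must be a mapping")
    unknown = set(raw) - set(GAMMSpec.__dataclass_fields__)
    if unknown:
        raise GammError(f"unknown model config keys {sorted(unknown)}")
    for key in ("smooths", "factors", "random"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return GAMMSpec(**raw)


@dataclass
class TermBlock:
    name: str
    kind: str  # 'intercept' | 'factor' | 'smooth' | 'random'
    sl: slice
    penalty: Optional[np.ndarray] = None  # within-block penalty (smooth/random)
    penalty_rank: int = 0
    penalty_logdet: float = 0.0
    # smooth bookkeeping
    knots: Optional[np.ndarray] = None
    center: Optional[np.ndarray] = None  # constraint null-space basis Z (k × k−1)
    x_observed: Optional[np.ndarray] = None
    # factor bookkeeping
    levels: Optional[tuple] = None


@dataclass
class Design:
    """Design matrix plus penalty/term bookkeeping for one model family."""

    X: np.ndarray
    blocks: list[TermBlock]
    spec: GAMMSpec
    n: int
    # correlation / variance-structure bookkeeping
    corr_groups: list[np.ndarray] = field(default_factory=list)  # row indices per block
    times: Optional[np.ndarray] = None
    var_group_codes: Optional[np.ndarray] = None
    var_group_levels: Optional[tuple] = None

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def block(self, name: str) -> TermBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise GammError(f"term {name!r} absent from model specification")

    @property
    def penalized(self) -> list[TermBlock]:
        return [b for b in self.blocks if b.penalty is not None]

    @property
    def null_dim(self) -> int:
        """Dimension of the total-penalty null space (unpenalized coefficients)."""
        dim = 0
        for b in self.blocks:
            ncol = b.sl.stop - b.sl.start
            dim += ncol - b.penalty_rank
        return dim


def build_design(spec: GAMMSpec, data: pd.DataFrame) -> Design:
    """Assemble the penalized design: centered spline bases with roughness
    penalties, treatment-coded factors, and ridge-penalized random
    intercepts, plus the AR(1)/variance-group bookkeeping."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: list[TermBlock] = [TermBlock("Intercept", "intercept", slice(0, 1))]
    pos = 1

    for name in spec.factors:
        codes, levels = pd.factorize(data[name], sort=True)
        if len(levels) < 2:
            raise GammError(f"factor {name!r} has fewer than 2 observed levels")
        dummies = np.eye(len(levels))[codes][:, 1:]  # treatment coding, first level ref
        cols.append(dummies)
        blocks.append(
            TermBlock(name, "factor", slice(pos, pos + dummies.shape[1]), levels=tuple(levels))
        )
        pos += dummies.shape[1]

    for name in spec.smooths:
        x = data[name].to_numpy(dtype=float)
        knots = _quantile_knots(x, spec.k)
        N = crs_basis(x, knots)
        _, S = _crs_matrices(knots)
        # centering constraint: column means of the basis sum to zero
        c = N.mean(axis=0)
        q, _ = np.linalg.qr(np.column_stack([c / np.linalg.norm(c)]), mode="complete")
        Z = q[:, 1:]
        Nc = N @ Z
        Sc = Z.T @ S @ Z
        eig = np.linalg.eigvalsh(Sc)
        rank = int((eig > eig.max() * 1e-10).sum())
        logdet = float(np.log(eig[eig > eig.max() * 1e-10]).sum())
        cols.append(Nc)
        blocks.append(
            TermBlock(
                name,
                "smooth",
                slice(pos, pos + Nc.shape[1]),
                penalty=Sc,
                penalty_rank=rank,
                penalty_logdet=logdet,
                knots=knots,
                center=Z,
                x_observed=x,
            )
        )
        pos += Nc.shape[1]

    for name in spec.random:
        codes, levels = pd.factorize(data[name], sort=True)
        if len(levels) < 2:
            raise GammError(f"random grouping {name!r} has fewer than 2 levels")
        Zr = np.eye(len(levels))[codes]
        cols.append(Zr)
        blocks.append(
            TermBlock(
                name,
                "random",
                slice(pos, pos + len(levels)),
                penalty=np.eye(len(levels)),
                penalty_rank=len(levels),
                penalty_logdet=0.0,
                levels=tuple(levels),
            )
        )
        pos += len(levels)

    X = np.hstack(cols)
    # rank sanity on the unpenalized (parametric) part
    p_par = blocks[0].sl.stop if len(blocks) == 1 else max(
        b.sl.stop for b in blocks if b.kind in ("intercept", "factor")
    )
    Xpar = X[:, :p_par]
    if np.linalg.matrix_rank(Xpar) < Xpar.shape[1]:
        raise GammError("parametric design block is rank deficient")
    if n <= p_par:
        raise GammError("more parametric coefficients than observations")
    smooth_cols = {}
    for b in blocks:
        if b.kind == "smooth":
            key = tuple(np.round(b.x_observed, 12))
            if key in smooth_cols:
                warnings.warn(
                    f"smooth covariates {smooth_cols[key]!r} and {b.name!r} are identical; "
                    "fit may be poorly identified",
                    stacklevel=2,
                )
            smooth_cols[key] = b.name

    corr_groups: list[np.ndarray] = []
    times = None
    if spec.ar1_group is not None and spec.ar1_group in data.columns:
        t_raw = data[spec.ar1_time]
        if np.issubdtype(t_raw.dtype, np.datetime64):
            times = (t_raw - t_raw.min()).dt.total_seconds().to_numpy() / 86400.0
        else:
            times = t_raw.to_numpy(dtype=float)
        for _, idx in data.groupby(spec.ar1_group, sort=True).indices.items():
            idx = np.asarray(idx)
            corr_groups.append(idx[np.argsort(times[idx], kind="stable")])
    else:
        corr_groups = [np.array([i]) for i in range(n)]

    var_codes = None
    var_levels = None
    if spec.variance_by is not None and spec.variance_by in data.columns:
        var_codes, lv = pd.factorize(data[spec.variance_by], sort=True)
        var_levels = tuple(lv)

    return Design(
        X=X,
        blocks=blocks,
        spec=spec,
        n=n,
        corr_groups=corr_groups,
        times=times,
        var_group_codes=var_codes,
        var_group_levels=var_levels,
    )


# --------------------------------------------------------------------------
# fitting


@dataclass
class GAMMFit:
    """Fitted additive mixed model."""

    design: Design
    beta: np.ndarray
    Vb: np.ndarray  # Bayesian covariance of beta
    sigma2: float
    lambdas: dict[str, float]
    phi: float
    var_weights: dict  # variance multiplier per group level
    edf: np.ndarray  # per-coefficient effective degrees of freedom
    edf1: np.ndarray  # alternative EDF (2·tr F − tr F²), used as test rank
    converged: bool
    reml: float
    n_iter: int

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def edf_total(self) -> float:
        return float(self.edf.sum())

    @property
    def df_residual(self) -> float:
        return self.n - self.edf_total

    def term_edf(self, name: str) -> float:
        return float(self.edf[self.design.block(name).sl].sum())

    def term_edf1(self, name: str) -> float:
        return float(self.edf1[self.design.block(name).sl].sum())

    def random_effect_sd(self, name: str) -> float:
        """Estimated standard deviation of a random-intercept term."""
        b = self.design.block(name)
        if b.kind != "random":
            raise GammError(f"{name!r} is not a random-intercept term")
        return float(np.sqrt(self.sigma2 / self.lambdas[name]))

    def smooth_values(self, name: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fitted centered smooth f̂(x) and its covariance."""
        b = self.design.block(name)
        if b.kind != "smooth":
            raise GammError(f"{name!r} is not a smooth term")
        N = crs_basis(np.asarray(x, dtype=float), b.knots) @ b.center
        f = N @ self.beta[b.sl]
        Vf = N @ self.Vb[b.sl, b.sl] @ N.T
        return f, Vf


def _whiten(design: Design, phi: float, weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factors of the residual covariance structure per block.

    ``weights`` holds a variance multiplier per observation.  Returns the
    list of per-block factors packed as (indices, L) and log|V|.
    """
    factors = []
    logdet = 0.0
    for idx in design.corr_groups:
        m = idx.size
        w = weights[idx]
        if m == 1 or phi == 0.0 or design.times is None:
            L = np.diag(np.sqrt(w))
        else:
            dt = np.abs(design.times[idx][:, None] - design.times[idx][None, :])
            C = phi**dt
            V = np.sqrt(w)[:, None] * C * np.sqrt(w)[None, :]
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                # coincident sampling times make the block singular; nugget
                V = V + np.eye(m) * 1e-6 * float(np.trace(V)) / m
                L = np.linalg.cholesky(V)
        factors.append((idx, L))
        logdet += float(2.0 * np.log(np.diag(L)).sum())
    return factors, logdet


def _apply_whitening(factors, M: np.ndarray) -> np.ndarray:
    out = np.empty_like(M, dtype=float)
    for idx, L in factors:
        out[idx] = linalg.solve_triangular(L, M[idx], lower=True)
    return out


def _penalty_total(design: Design, lam: np.ndarray) -> np.ndarray:
    S = np.zeros((design.p, design.p))
    for lj, b in zip(lam, design.penalized):
        S[b.sl, b.sl] += lj * b.penalty
    return S


def _reml_core(
    design: Design, Xw: np.ndarray, yw: np.ndarray, lam: np.ndarray, logdetV: float
):
    """Profiled Gaussian REML criterion and fit quantities for fixed structure."""
    XtX = Xw.T @ Xw
    A = XtX + _penalty_total(design, lam)
    try:
        cf = linalg.cho_factor(A)
    except linalg.LinAlgError:
        A = A + np.eye(design.p) * 1e-8 * np.trace(A) / design.p
        cf = linalg.cho_factor(A)
    beta = linalg.cho_solve(cf, Xw.T @ yw)
    resid = yw - Xw @ beta
    pen = sum(
        lj * float(beta[b.sl] @ b.penalty @ beta[b.sl])
        for lj, b in zip(lam, design.penalized)
    )
    P = float(resid @ resid) + pen
    nmp = design.n - design.null_dim
    sigma2 = P / nmp
    log_det_A = 2.0 * float(np.log(np.diag(cf[0])).sum())
    log_det_S = sum(
        b.penalty_rank * np.log(lj) + b.penalty_logdet
        for lj, b in zip(lam, design.penalized)
    )
    reml = (
        nmp * (np.log(2.0 * np.pi * sigma2) + 1.0) + log_det_A - log_det_S + logdetV
    )
    return reml, beta, sigma2, cf, XtX


def _optimize_lambdas(design, Xw, yw, logdetV, rho0: np.ndarray) -> np.ndarray:
    if rho0.size == 0:
        return rho0

    def crit(rho):
        return _reml_core(design, Xw, yw, np.exp(rho), logdetV)[0]

    res = optimize.minimize(
        crit, rho0, method="L-BFGS-B", bounds=[(-12.0, 18.0)] * rho0.size,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    return res.x


def fit_gamm(design: Design, response: np.ndarray) -> GAMMFit:
    """Fit the penalized additive mixed model by REML.

    Smoothing parameters and random-intercept precisions are optimized by
    quasi-Newton REML; the AR(1) parameter and the per-group variance
    multipliers are updated in an outer loop (REML line search for φ,
    moment update for the weights) until the relative change in all
    structural parameters falls below the spec tolerance.  Non-convergence
    is flagged, not raised.
    """
    y = np.asarray(response, dtype=float)
    if y.shape != (design.n,):
        raise GammError(f"response length {y.size} != design rows {design.n}")
    if np.ptp(y) == 0:
        raise GammError("response is constant; model degenerate")
    spec = design.spec
    n_pen = len(design.penalized)
    rho = np.zeros(n_pen)
    phi = 0.0
    has_ar = spec.ar1_group is not None and design.times is not None and any(
        g.size > 1 for g in design.corr_groups
    )
    n_vg = len(design.var_group_levels) if design.var_group_levels else 0
    vmult = np.ones(max(n_vg, 1))
    weights = np.ones(design.n)

    converged = False
    state = np.concatenate([rho, [phi], np.log(vmult)])
    reml = np.inf
    beta = sigma2 = cf = XtX = None
    it = 0
    for it in range(1, spec.max_iter + 1):
        factors, logdetV = _whiten(design, phi, weights)
        Xw = _apply_whitening(factors, design.X)
        yw = _apply_whitening(factors, y[:, None])[:, 0]
        rho = _optimize_lambdas(design, Xw, yw, logdetV, rho)
        reml, beta, sigma2, cf, XtX = _reml_core(design, Xw, yw, np.exp(rho), logdetV)

        if not has_ar and n_vg == 0:
            converged = True
            break

        raw_resid = y - design.X @ beta

        if n_vg > 0:
            # decorrelate with the current phi but unit weights, then take
            # group mean squares relative to the pooled mean square
            fac_c, _ = _whiten(design, phi, np.ones(design.n))
            e = _apply_whitening(fac_c, raw_resid[:, None])[:, 0]
            pooled = float(np.mean(e**2))
            new_v = np.array(
                [
                    np.mean(e[design.var_group_codes == g] ** 2) / pooled
                    for g in range(n_vg)
                ]
            )
            vmult = np.clip(new_v, 1e-3, 1e3)
            weights = vmult[design.var_group_codes]

        if has_ar:

            def phi_crit(p):
                fac, ldv = _whiten(design, p, weights)
                Xw_ = _apply_whitening(fac, design.X)
                yw_ = _apply_whitening(fac, y[:, None])[:, 0]
                return _reml_core(design, Xw_, yw_, np.exp(rho), ldv)[0]

            res = optimize.minimize_scalar(phi_crit, bounds=(0.0, 0.98), method="bounded")
            phi = float(res.x)

        new_state = np.concatenate([rho, [phi], np.log(vmult)])
        delta = np.max(np.abs(new_state - state) / (1.0 + np.abs(state)))
        state = new_state
        if delta < spec.tol:
            converged = True
            break

    if not converged:
        logger.warning("GAMM did not converge in %d outer iterations", spec.max_iter)

    # final pass with the converged structure
    factors, logdetV = _whiten(design, phi, weights)
    Xw = _apply_whitening(factors, design.X)
    yw = _apply_whitening(factors, y[:, None])[:, 0]
    reml, beta, sigma2, cf, XtX = _reml_core(design, Xw, yw, np.exp(rho), logdetV)
    Ainv = linalg.cho_solve(cf, np.eye(design.p))
    F = Ainv @ XtX
    edf = np.diag(F).copy()
    edf1 = 2.0 * edf - np.diag(F @ F)
    Vb = sigma2 * Ainv

    lambdas = {b.name: float(lj) for lj, b in zip(np.exp(rho), design.penalized)}
    vw = (
        {lv: float(v) for lv, v in zip(design.var_group_levels, vmult)}
        if n_vg
        else {}
    )
    return GAMMFit(
        design=design,
        beta=beta,
        Vb=Vb,
        sigma2=sigma2,
        lambdas=lambdas,
        phi=phi if has_ar else 0.0,
        var_weights=vw,
        edf=edf,
        edf1=edf1,
        converged=converged,
        reml=reml,
        n_iter=it,
    )


# --------------------------------------------------------------------------
# inference


def term_pvalue(fit: GAMMFit, term: str) -> float:
    """Wald-type p-value for one model term.

    Smooths: test of the fitted smooth evaluated at the observed covariate
    values, using a fractional-rank pseudo-inverse of its covariance — rank
    equal to the term's alternative EDF, with the trailing eigendirection
    downweighted by the fractional part — referred to an F distribution on
    (rank, residual) degrees of freedom.  This is the standard remedy for
    the anti-conservatism of naive Wald tests on penalized smooths.
    Factors: joint Wald F-test of the level contrasts against the residual
    degrees of freedom.
    """
    b = fit.design.block(term)
    if b.kind == "smooth":
        f, Vf = fit.smooth_values(term, b.x_observed)
        vals, vecs = np.linalg.eigh(Vf)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        rank_max = int((vals > vals[0] * 1e-10).sum())
        r = float(min(max(fit.term_edf1(term), 1.0), rank_max))
        k = int(np.floor(r))
        nu = r - k
        proj = vecs[:, : min(k + 1, rank_max)].T @ f
        T = float(np.sum(proj[:k] ** 2 / vals[:k]))
        if nu > 1e-8 and k < rank_max:
            T += float(nu * proj[k] ** 2 / vals[k])
        return float(stats.f.sf(T / r, r, fit.df_residual))
    if b.kind == "factor":
        bb = fit.beta[b.sl]
        V = fit.Vb[b.sl, b.sl]
        q = bb.size
        stat = float(bb @ linalg.solve(V, bb, assume_a="pos")) / q
        return float(stats.f.sf(stat, q, fit.df_residual))
    raise GammError(f"term {term!r} is not a testable fixed term")


def classify_effect_direction(
    fit: GAMMFit, term: str, alpha: float = ALPHA, edf_linear: float = 1.5
) -> str:
    """Classify a smooth as positive / negative / nonlinear / ns.

    Non-significant terms (p ≥ alpha) are ``ns``.  Significant terms get a
    direction when the fitted smooth is monotone across the bulk of the
    observed covariate range (the inner 95%, which keeps sparsely supported
    boundary wiggle from masking a clear trend): ``positive`` / ``negative``
    accordingly.  Significant but non-monotone (unimodal or more complex)
    smooths are ``nonlinear``.  Terms with EDF ≤ ``edf_linear`` are
    effectively straight lines and always receive a direction.
    Non-converged fits cannot be classified.
    """
    if not fit.converged:
        raise GammError("cannot classify effect directions of a non-converged fit")
    p = term_pvalue(fit, term)
    if p >= alpha:
        return "ns"
    b = fit.design.block(term)
    near_linear = fit.term_edf(term) <= edf_linear
    if near_linear:
        lo, hi = b.x_observed.min(), b.x_observed.max()
    else:
        lo, hi = np.quantile(b.x_observed, [0.025, 0.975])
    grid = np.linspace(lo, hi, 101)
    f, _ = fit.smooth_values(term, grid)
    d = np.diff(f)
    tol = 1e-3 * float(np.ptp(f)) if np.ptp(f) > 0 else 1e-10
    if np.all(d >= -tol):
        return "positive"
    if np.all(d <= tol):
        return "negative"
    return "nonlinear"


@dataclass(frozen=True)
class MarginalMeans:
    """Factor-level marginal means with their covariance."""

    factor: str
    levels: tuple
    estimates: np.ndarray
    cov: np.ndarray
    df: float


@dataclass(frozen=True)
class ContrastResult:
    """One Tukey-adjusted pairwise contrast of factor levels."""

    level_a: str
    level_b: str
    estimate: float
    se: float
    t: float
    p_unadjusted: float
    p_adjusted: float


def estimated_marginal_means(fit: GAMMFit, factor: str = "Area") -> MarginalMeans:
    """Model-predicted means per factor level at reference covariates.

    Smooth covariates sit at their observed means, other factors get
    balanced (equal) weights over their levels, random intercepts are set
    to zero (population level).
    """
    design = fit.design
    fb = design.block(factor)
    if fb.kind != "factor":
        raise GammError(f"{factor!r} is not a parametric factor in the model")
    levels = fb.levels
    L = np.zeros((len(levels), design.p))
    L[:, 0] = 1.0  # intercept
    for b in design.blocks:
        if b.kind == "factor" and b.name != factor:
            L[:, b.sl] = 1.0 / len(b.levels)  # balanced over non-reference dummies
        elif b.kind == "smooth":
            row = crs_basis(np.array([float(b.x_observed.mean())]), b.knots) @ b.center
            L[:, b.sl] = row
    ncol = fb.sl.stop - fb.sl.start
    for i in range(len(levels)):
        if i > 0:  # treatment coding: first level is reference
            L[i, fb.sl.start + i - 1] = 1.0
    assert ncol == len(levels) - 1
    est = L @ fit.beta
    cov = L @ fit.Vb @ L.T
    return MarginalMeans(
        factor=factor, levels=levels, estimates=est, cov=cov, df=fit.df_residual
    )


def tukey_pairwise(emm: MarginalMeans) -> list[ContrastResult]:
    """All pairwise level contrasts with studentized-range adjustment.

    The adjusted p for a contrast with t-statistic t among k level means is
    P(Q_{k,df} ≥ |t|·√2), which reproduces classical Tukey HSD under equal
    sample sizes and reduces to the unadjusted two-sided t-test at k=2.
    """
    k = len(emm.levels)
    if k < 2:
        raise GammError("pairwise contrasts require at least two levels")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(emm.estimates[i] - emm.estimates[j])
            var = float(emm.cov[i, i] + emm.cov[j, j] - 2.0 * emm.cov[i, j])
            if var <= 0:
                raise GammError("singular covariance among marginal means")
            se = np.sqrt(var)
            t = diff / se
            p_un = 2.0 * float(stats.t.sf(abs(t), emm.df))
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, emm.df))
            out.append(
                ContrastResult(
                    level_a=str(emm.levels[i]),
                    level_b=str(emm.levels[j]),
                    estimate=diff,
                    se=se,
                    t=t,
                    p_unadjusted=p_un,
                    p_adjusted=min(1.0, max(p_adj, p_un)),
                )
            )
    return out


def summarize_terms(fit: GAMMFit) -> pd.DataFrame:
    """Per-term p-values, EDFs, and effect-direction codes (table layout)."""
    rows = []
    for b in fit.design.blocks:
        if b.kind == "smooth":
            rows.append(
                {
                    "term": b.name,
                    "kind": "smooth",
                    "edf": fit.term_edf(b.name),
                    "p_value": term_pvalue(fit, b.name),
                    "direction": classify_effect_direction(fit, b.name, fit.design.spec.alpha),
                }
            )
        elif b.kind == "factor":
            rows.append(
                {
                    "term": b.name,
                    "kind": "factor",
                    "edf": fit.term_edf(b.name),
                    "p_value": term_pvalue(fit, b.name),
                    "direction": "",
                }
            )
    return pd.DataFrame(rows)
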