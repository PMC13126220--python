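"""Marginal maximum likelihood for one-stage meta-analytic CFA with means.

Model.  Study i contributes the effect-size vector y_i = [vech(S_i); ybar_i]
(length d), modeled as

    y_i ~ N( m(theta, x_i),  T^2 + V_i )

where m stacks the model-implied moments [vech(Sigma); mu] of a (possibly
moderated) CFA evaluated at the study's moderator values x_i, V_i is the
known within-study sampling covariance, and T^2 is the between-studies
covariance of the random effects:

* covariance-effect block: diagonal (between-study variances of the
  covariances; their covariances fixed at 0), parameterized on the log scale;
* mean-effect block: unstructured symmetric, parameterized by its Cholesky
  factor (log-diagonal), hence positive semidefinite by construction;
* cross block: fixed at 0 by default; optionally freed (a Schur-complement
  parameterization keeps the joint matrix PSD).

Estimation.  The -2 log-likelihood is profiled: for fixed heterogeneity
parameters the mean-structure parameters solve a generalized-least-squares
problem (damped Gauss-Newton; exact in one step for the saturated model),
and the outer optimization over the heterogeneity parameters runs L-BFGS-B
with the analytic envelope gradient.  Derivatives of the moment map and of
T^2 use complex-step differentiation, exact to machine precision for these
polynomial/exponential maps.

Model comparison uses -2LL differences against a saturated means-and-
covariances baseline with matching moderation status (chi-square, RMSEA),
chi-square difference tests between nested invariance models, AIC/BIC, and
Wald tests on single parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cfa_model import CFASpec
from .summary_data import (
    StudyRecord,
    compute_sampling_covariance,
    effect_vector,
    vech_indices,
    vech_labels,
)

__all__ = [
    "HeterogeneitySpec",
    "FitOptions",
    "FitResult",
    "PreparedData",
    "prepare_data",
    "marginal_loglik",
    "fit",
    "fit_saturated",
    "fit_invariance_ladder",
    "lrt",
    "information_criteria",
    "rmsea",
    "wald_test",
    "smd",
]

_CSTEP = 1e-100
_LOG2PI = float(np.log(2 * np.pi))
_PENALTY = 1e12


# ---------------------------------------------------------------------------
# heterogeneity structure
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneitySpec:
    """Structure of the between-studies covariance matrix T^2 (see module
    docstring).  ``free_cross=True`` additionally frees the covariances
    between the mean effects and the covariance effects."""

    p: int
    free_cross: bool = False

    @property
    def ns(self) -> int:
        return self.p * (self.p + 1) // 2

    @property
    def d(self) -> int:
        return self.ns + self.p

    @property
    def n_params(self) -> int:
        return self.ns + self.ns + (self.ns * self.p if self.free_cross else 0)

    @property
    def param_names(self) -> list[str]:
        labels = vech_labels([f"y{i + 1}" for i in range(self.p)])
        names = [f"log_tau2_s[{lab}]" for lab in labels]
        vr, vc = vech_indices(self.p)
        names += [
            (f"log_chol_m[{r + 1},{c + 1}]" if r == c else f"chol_m[{r + 1},{c + 1}]")
            for r, c in zip(vr, vc)
        ]
        if self.free_cross:
            names += [
                f"cross[{i + 1},{j + 1}]" for i in range(self.ns) for j in range(self.p)
            ]
        return names

    @property
    def bounds(self) -> list[tuple[float, float]]:
        vr, vc = vech_indices(self.p)
        b = [(-30.0, 8.0)] * self.ns
        b += [(-15.0, 8.0) if r == c else (-50.0, 50.0) for r, c in zip(vr, vc)]
        if self.free_cross:
            b += [(-50.0, 50.0)] * (self.ns * self.p)
        return b

    def build(self, eta: np.ndarray) -> np.ndarray:
        """T^2 from the unconstrained parameter vector; batched, complex-safe."""
        eta = np.asarray(eta)
        lead = eta.shape[:-1]
        p, ns, d = self.p, self.ns, self.d
        T2 = np.zeros(lead + (d, d), dtype=eta.dtype)
        idx = np.arange(ns)
        T2[..., idx, idx] = np.exp(eta[..., :ns])
        L = self._chol_factor(eta)
        M = L @ np.swapaxes(L, -1, -2)
        if self.free_cross:
            C = eta[..., ns + ns :].reshape(lead + (ns, p))
            Dinv = np.exp(-eta[..., :ns])
            M = M + np.einsum("...ia,...i,...ib->...ab", C, Dinv, C)
            T2[..., :ns, ns:] = C
            T2[..., ns:, :ns] = np.swapaxes(C, -1, -2)
        T2[..., ns:, ns:] = M
        return T2

    def _chol_factor(self, eta: np.ndarray) -> np.ndarray:
        """Lower-triangular factor of the mean-effect block (log diagonal)."""
        p, ns = self.p, self.ns
        vr, vc = vech_indices(p)
        vals = eta[..., ns : ns + self.ns]
        diag = vr == vc
        L = np.zeros(eta.shape[:-1] + (p, p), dtype=eta.dtype)
        L[..., vr[diag], vc[diag]] = np.exp(vals[..., diag])
        L[..., vr[~diag], vc[~diag]] = vals[..., ~diag]
        return L

    def build_jac(self, eta: np.ndarray) -> np.ndarray:
        """d T^2 / d eta_a, shape (n_params, d, d), by complex step."""
        nh = self.n_params
        et = np.asarray(eta, dtype=float)[None, :] + 1j * _CSTEP * np.eye(nh)
        return self.build(et).imag / _CSTEP

    def grad_quadratic(self, eta: np.ndarray, S: np.ndarray) -> np.ndarray:
        """Gradient of tr(T^2(eta) S) for symmetric S: the analytic form of
        einsum('aij,ij->a', build_jac(eta), S), avoiding the complex step
        for the default (no free cross block) structure."""
        if self.free_cross:
            D = self.build_jac(eta)
            return D.reshape(self.n_params, -1) @ np.asarray(S, dtype=float).ravel()
        ns, p = self.ns, self.p
        Ssym = (S + S.T) / 2.0
        g_zeta = np.exp(eta[:ns]) * np.diagonal(Ssym)[:ns]
        L = self._chol_factor(eta)
        SL = 2.0 * Ssym[ns:, ns:] @ L  # tr(S (E L' + L E')) = 2 (S L)_rc
        vr, vc = vech_indices(p)
        g_L = SL[vr, vc]
        diag = vr == vc
        g_L[diag] *= L[vr[diag], vc[diag]]  # chain rule through the log diagonal
        return np.concatenate([g_zeta, g_L])

    def start(self, prep: "PreparedData") -> np.ndarray:
        """Method-of-moments starting values from the observed between-study
        spread of the effect sizes (excess over the average V_i), floored."""
        ns, p = self.ns, self.p
        y, V = prep.y, prep.V
        if prep.k < 3:  # no usable between-study spread
            out = np.concatenate([np.full(ns, np.log(0.01)),
                                  self._chol_params(0.1 * np.eye(p))])
            if self.free_cross:
                out = np.concatenate([out, np.zeros(ns * p)])
            return out
        spread = np.var(y, axis=0, ddof=1) - V[:, np.arange(prep.d), np.arange(prep.d)].mean(0)
        zeta = np.log(np.clip(spread[:ns], 1e-5, 1e3))
        Bm = np.cov(y[:, ns:], rowvar=False).reshape(p, p) - V[:, ns:, ns:].mean(0)
        w, Q = np.linalg.eigh((Bm + Bm.T) / 2)
        Bm = (Q * np.clip(w, 1e-4, None)) @ Q.T
        L = np.linalg.cholesky(Bm)
        vr, vc = vech_indices(p)
        lpar = np.array([np.log(L[r, c]) if r == c else L[r, c] for r, c in zip(vr, vc)])
        out = np.concatenate([zeta, lpar])
        if self.free_cross:
            out = np.concatenate([out, np.zeros(ns * p)])
        return out

    def _chol_params(self, M: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(M)
        vr, vc = vech_indices(self.p)
        return np.array([np.log(L[r, c]) if r == c else L[r, c] for r, c in zip(vr, vc)])


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparedData:
    y: np.ndarray  # (k, d), zero-padded at absent entries
    V: np.ndarray  # (k, d, d), within-study sampling covariances
    present: np.ndarray  # (k, d) bool
    n: np.ndarray  # (k,)
    x: dict  # moderator name -> (k,) values
    study_ids: list[str]
    p: int

    @property
    def k(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.y.shape[1]

    @property
    def complete(self) -> bool:
        return bool(self.present.all())

    @property
    def N_total(self) -> int:
        return int(self.n.sum())

    def moderator_matrix(self, names: list[str]) -> np.ndarray:
        missing = [m for m in names if m not in self.x]
        if missing:
            raise ValueError(f"moderator(s) {missing} not present in the data")
        if not names:
            return np.zeros((self.k, 0))
        return np.column_stack([self.x[m] for m in names])


def prepare_data(records: list[StudyRecord], v_source: str = "pooled") -> PreparedData:
    """Validate records, drop flagged studies, assemble y_i and V_i.

    ``v_source`` selects the covariance matrix plugged into the normal-theory
    sampling-covariance formula: ``"pooled"`` (default) uses the
    (n-1)-weighted pooled sample covariance across studies, ``"study"`` each
    study's own S.  The pooled plug-in keeps the GLS weights uncorrelated
    with the observations; the own-S plug-in attenuates pooled covariances
    by O(1/n) because randomly large covariances receive randomly large
    sampling variances.
    """
    if v_source not in ("pooled", "study"):
        raise ValueError(f"unknown v_source {v_source!r}")
    kept = [r for r in records if r.ok]
    dropped = [r for r in records if not r.ok]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} flagged studies: "
            + ", ".join(r.study_id for r in dropped),
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no valid studies to analyze")
    p = kept[0].p
    mods = sorted(kept[0].moderators)
    Spool = None
    if v_source == "pooled":
        wsum = np.zeros((p, p))
        Ssum = np.zeros((p, p))
        for r in kept:
            obs = np.outer(r.observed_mask, r.observed_mask) & ~np.isnan(r.S)
            w = (r.n - 1) * obs
            Ssum += np.where(obs, np.nan_to_num(r.S), 0.0) * w
            wsum += w
        with np.errstate(invalid="ignore"):
            Spool = np.where(wsum > 0, Ssum / np.where(wsum > 0, wsum, 1.0), np.nan)
    ys, Vs, pres, ns = [], [], [], []
    for r in kept:
        if r.p != p:
            raise ValueError(f"study {r.study_id}: inconsistent number of variables")
        if sorted(r.moderators) != mods:
            raise ValueError(f"study {r.study_id}: inconsistent moderator names")
        ev = effect_vector(r)
        Splug = r.S if Spool is None else np.where(np.isnan(Spool), r.S, Spool)
        sv = compute_sampling_covariance(Splug, r.n, r.observed_mask)
        if not sv.valid:
            warnings.warn(f"excluding study {r.study_id}: singular covariance", stacklevel=2)
            continue
        ys.append(np.where(ev.present, ev.values, 0.0))
        Vs.append(sv.V)
        pres.append(ev.present)
        ns.append(r.n)
    x = {m: np.array([r.moderators[m] for r in kept], dtype=float) for m in mods}
    return PreparedData(
        y=np.array(ys),
        V=np.array(Vs),
        present=np.array(pres),
        n=np.array(ns),
        x=x,
        study_ids=[r.study_id for r in kept],
        p=p,
    )


# ---------------------------------------------------------------------------
# saturated mean model (linear in its parameters)
# ---------------------------------------------------------------------------


class SaturatedMeanModel:
    """Unconstrained means-and-covariances structure: every effect-size mean
    free, optionally all regressed on the moderators.  Presents the same
    interface as a compiled CFA model.  The moment map is linear in the
    parameters, so the profile step solves it in closed form."""

    linear = True

    def __init__(self, p: int, moderators: list[str] = ()):  # noqa: B006-like default ok
        self.p = p
        self.d = p * (p + 1) // 2 + p
        self.moderators = list(moderators)
        labels = vech_labels([f"y{i + 1}" for i in range(p)]) + [
            f"mean(y{i + 1})" for i in range(p)
        ]
        names = [f"m[{lab}]" for lab in labels]
        for mod in self.moderators:
            names += [f"m[{lab}]@{mod}" for lab in labels]
        from .cfa_model import ParameterVector

        self.theta = ParameterVector(names=names, start=np.zeros(len(names)))
        self.t = len(names)

    def moments(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = self.d
        base = theta[..., None, :d]
        out = np.broadcast_to(base, theta.shape[:-1] + (X.shape[0], d)).astype(theta.dtype)
        out = out.copy()
        for m in range(len(self.moderators)):
            sl = theta[..., None, (m + 1) * d : (m + 2) * d]
            out = out + sl * X[:, m][:, None]
        return out

    def moments_and_jac(self, theta: np.ndarray, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        G, d = X.shape[0], self.d
        m0 = self.moments(theta, X)
        J = np.zeros((G, d, self.t))
        J[:, np.arange(d), np.arange(d)] = 1.0
        for m in range(len(self.moderators)):
            J[:, np.arange(d), (m + 1) * d + np.arange(d)] = X[:, m][:, None]
        return m0, J


# ---------------------------------------------------------------------------
# likelihood internals
# ---------------------------------------------------------------------------


def _omega_terms(T2: np.ndarray, prep: PreparedData):
    """Per-study padded inverses, log-determinants and dimension constant of
    Omega_i = T^2 + V_i restricted to the present entries.  Returns
    (Oinv (k,d,d), logdets (k,), const, ok)."""
    k, d = prep.k, prep.d
    if prep.complete:
        Omega = T2[None, :, :] + prep.V
        try:
            L = np.linalg.cholesky(Omega)
        except np.linalg.LinAlgError:
            return None, None, None, False
        logdets = 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(-1)
        Oinv = np.linalg.inv(Omega)
        return Oinv, logdets, k * d * _LOG2PI, True
    Oinv = np.zeros((k, d, d))
    logdets = np.zeros(k)
    const = 0.0
    for i in range(k):
        m = prep.present[i]
        Om = (T2 + prep.V[i])[np.ix_(m, m)]
        sign, ld = np.linalg.slogdet(Om)
        if sign <= 0:
            return None, None, None, False
        Oinv[np.ix_([i], m, m)] = np.linalg.inv(Om)[None]
        logdets[i] = ld
        const += m.sum() * _LOG2PI
    return Oinv, logdets, const, True


def _aggregates(Oinv: np.ndarray, y: np.ndarray, group_masks: list[np.ndarray]):
    """A_g = sum_i Oinv_i, b_g = sum_i Oinv_i y_i over studies in group g."""
    u = (Oinv @ y[:, :, None])[:, :, 0]
    A = np.stack([Oinv[m].sum(0) for m in group_masks])
    b = np.stack([u[m].sum(0) for m in group_masks])
    c0 = float((u * y).sum())  # sum_i y' Oinv y
    return A, b, c0


def _profile_theta(model, A, b, XU, theta0, tol=1e-11, maxiter=100):
    """Minimize g(theta) = sum_g [m_g' A_g m_g - 2 b_g' m_g] by damped
    Gauss-Newton with an Armijo line search.  Exact in one step when the
    moment map is linear (saturated model)."""
    theta = np.asarray(theta0, dtype=float).copy()
    if model.t == 0:
        m = model.moments(theta, XU)
        return theta, float(np.einsum("gi,gij,gj->", m, A, m) - 2 * np.sum(b * m)), True

    if getattr(model, "linear", False):
        # m_g = J_g theta exactly: generalized least squares in closed form
        _, J = model.moments_and_jac(np.zeros(model.t), XU)
        Jt = np.swapaxes(J, -1, -2)
        H = (Jt @ A @ J).sum(0)
        rhs = (Jt @ b[:, :, None])[:, :, 0].sum(0)
        try:
            theta = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            theta = np.linalg.lstsq(H, rhs, rcond=None)[0]
        g = float(theta @ H @ theta - 2.0 * rhs @ theta)
        return theta, g, True

    def gval(th):
        m = model.moments(th, XU)
        return float(((A @ m[:, :, None])[:, :, 0] * m).sum() - 2 * np.sum(b * m))

    g = gval(theta)
    converged = False
    scale = max(1.0, float(np.max(np.abs(b))))
    for _ in range(maxiter):
        m0, J = model.moments_and_jac(theta, XU)
        resid_w = (A @ m0[:, :, None])[:, :, 0] - b
        grad = 2.0 * (J * resid_w[:, :, None]).sum((0, 1))
        if np.max(np.abs(grad)) < 1e-10 * scale:
            converged = True
            break
        Jt = np.swapaxes(J, -1, -2)
        H = 2.0 * (Jt @ A @ J).sum(0)
        lam = 0.0
        for _damp in range(8):
            try:
                step = np.linalg.solve(H + lam * np.eye(model.t), -grad)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6 * np.trace(H) / model.t)
                continue
            alpha, ok = 1.0, False
            gdir = float(grad @ step)
            if gdir >= 0:  # not a descent direction; increase damping
                lam = max(lam * 10.0, 1e-6 * abs(np.trace(H)) / model.t)
                continue
            for _ls in range(25):
                gnew = gval(theta + alpha * step)
                if gnew <= g + 1e-4 * alpha * gdir:
                    ok = True
                    break
                alpha *= 0.5
            if ok:
                theta = theta + alpha * step
                gchange = g - gnew
                g = gnew
                break
            lam = max(lam * 10.0, 1e-6 * abs(np.trace(H)) / model.t)
        else:
            break
        if gchange <= tol * (1.0 + abs(g)):
            converged = True
            break
    return theta, g, converged


def _unique_groups(X: np.ndarray):
    if X.shape[1] == 0:
        return np.zeros((1, 0)), np.zeros(X.shape[0], dtype=int)
    XU, gidx = np.unique(X, axis=0, return_inverse=True)
    return XU, gidx.ravel()


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Optimizer settings; defaults favor accuracy over speed."""

    outer_maxiter: int = 500
    ftol: float = 1e-11
    gtol: float = 1e-7
    inner_tol: float = 1e-11
    restarts: int = 1  # extra jittered starts on non-convergence
    jitter: float = 0.1
    seed: int = 0
    compute_se: bool = True


@dataclass
class FitResult:
    """Estimates and diagnostics of one marginal-ML fit."""

    model: str
    params: dict  # mean-structure estimates by name
    het_params: dict  # heterogeneity estimates (transformed scale) by name
    T2: np.ndarray
    minus2LL: float
    n_mean_free: int
    n_free: int  # incl. heterogeneity parameters
    df: int
    converged: bool
    k: int
    N_total: int
    se: dict | None = None
    message: str = ""
    n_outer_iter: int = 0
    theta: np.ndarray | None = None
    eta: np.ndarray | None = None
    boundary: list = field(default_factory=list)

    def param_table(self) -> pd.DataFrame:
        rows = []
        for name, est in {**self.params, **self.het_params}.items():
            se = (self.se or {}).get(name)
            z = est / se if se else np.nan
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": se if se is not None else np.nan,
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _as_prepared(data) -> PreparedData:
    return data if isinstance(data, PreparedData) else prepare_data(data)


def _data_driven_starts(model, prep: PreparedData) -> np.ndarray:
    """Pooled-moment starting values: intercepts at pooled means, residual
    variances at half the pooled variances, loadings at the spec start."""
    theta0 = model.theta.start.copy()
    w = prep.n / prep.N_total
    ypool = w @ prep.y
    ns = prep.d - prep.p
    vr, vc = vech_indices(prep.p)
    pooled_var = ypool[:ns][vr == vc]
    for j, name in enumerate(model.theta.names):
        if name.startswith("psi[") and "@" not in name:
            i = int(name.split("[")[1].split(",")[0]) - 1
            theta0[j] = max(pooled_var[i] / 2.0, 1e-3)
        elif name.startswith("tau[") and "@" not in name:
            i = int(name.split("[")[1].split("]")[0]) - 1
            theta0[j] = ypool[ns + i]
        elif name.startswith("m["):
            if "@" not in name:
                theta0[j] = ypool[j % prep.d]
    return theta0


def _fit_core(model, het: HeterogeneitySpec, prep: PreparedData, options: FitOptions,
              eta0=None, theta0=None, model_name="model", fix_eta=None):
    X = prep.moderator_matrix(model.moderators)
    XU, gidx = _unique_groups(X)
    G = XU.shape[0]
    group_masks = [gidx == g for g in range(G)]
    if eta0 is None and fix_eta is None:
        eta0 = het.start(prep)
    if theta0 is None:
        theta0 = _data_driven_starts(model, prep)
    state = {"theta": np.asarray(theta0, dtype=float).copy(), "inner_ok": True}

    def objective(eta):
        T2 = het.build(eta)
        Oinv, logdets, const, ok = _omega_terms(T2, prep)
        if not ok:
            return _PENALTY, np.zeros_like(eta)
        A, b, c0 = _aggregates(Oinv, prep.y, group_masks)
        theta, g, inner_ok = _profile_theta(
            model, A, b, XU, state["theta"], tol=options.inner_tol
        )
        state["theta"], state["inner_ok"] = theta, inner_ok
        neg2ll = const + float(logdets.sum()) + c0 + g
        # envelope gradient wrt heterogeneity parameters
        m_hat = model.moments(theta, XU)
        r = prep.y - m_hat[gidx]
        u = (Oinv @ r[:, :, None])[:, :, 0]
        grad = het.grad_quadratic(eta, Oinv.sum(0) - u.T @ u)
        return neg2ll, grad

    if fix_eta is not None:
        # heterogeneity held fixed: profile the mean structure only
        fix_eta = np.asarray(fix_eta, dtype=float)
        f0, _ = objective(fix_eta)
        res = optimize.OptimizeResult(
            x=fix_eta, fun=f0, success=state["inner_ok"], nit=0,
            message="heterogeneity parameters fixed",
        )
        best = (res, state["theta"].copy(), bool(state["inner_ok"] and f0 < _PENALTY / 2))
    else:
        best = None
    rng = np.random.default_rng(options.seed)
    for attempt in range(1 + options.restarts) if fix_eta is None else ():
        e0 = eta0 if attempt == 0 else eta0 + options.jitter * rng.standard_normal(eta0.shape)
        if attempt > 0:
            state["theta"] = np.asarray(theta0, dtype=float).copy()
        res = optimize.minimize(
            objective,
            e0,
            jac=True,
            method="L-BFGS-B",
            bounds=het.bounds,
            options={
                "maxiter": options.outer_maxiter,
                "ftol": options.ftol,
                "gtol": options.gtol,
                "maxcor": 20,
            },
        )
        if not res.success and hasattr(res, "jac"):
            # accept an optimum pinned at bounds: projected gradient ~ 0
            lo = np.array([b[0] for b in het.bounds])
            hi = np.array([b[1] for b in het.bounds])
            pg = np.asarray(res.jac, dtype=float).copy()
            pg[(res.x <= lo + 1e-9) & (pg > 0)] = 0.0
            pg[(res.x >= hi - 1e-9) & (pg < 0)] = 0.0
            if np.max(np.abs(pg)) < 5e-3:
                res.success = True
                res.message = str(res.message) + " [projected gradient ~ 0 at bounds]"
        conv = bool(res.success) and state["inner_ok"] and res.fun < _PENALTY / 2
        cand = (res, state["theta"].copy(), conv)
        if best is None or res.fun < best[0].fun - 1e-10:
            best = cand
        if conv and attempt == 0:
            break
    res, theta_hat, converged = best
    eta_hat = res.x
    theta_hat = _canonicalize_signs(model, theta_hat)
    minus2LL = float(res.fun)

    lower = np.array([b[0] for b in het.bounds])
    upper = np.array([b[1] for b in het.bounds])
    on_bound = [
        het.param_names[j]
        for j in range(len(eta_hat))
        if eta_hat[j] <= lower[j] + 1e-6
        or eta_hat[j] >= upper[j] - 1e-6
        # log-scale variances this small are at the tau^2 = 0 boundary
        or (het.param_names[j].startswith("log_") and eta_hat[j] < -18.0)
    ]

    n_mods = len(model.moderators)
    n_mean_free = model.t
    df = prep.d * (1 + n_mods) - n_mean_free
    result = FitResult(
        model=model_name,
        params=dict(zip(model.theta.names, theta_hat)),
        het_params=dict(zip(het.param_names, eta_hat)),
        T2=het.build(eta_hat),
        minus2LL=minus2LL,
        n_mean_free=n_mean_free,
        n_free=n_mean_free + het.n_params,
        df=df,
        converged=converged,
        k=prep.k,
        N_total=prep.N_total,
        message=str(res.message),
        n_outer_iter=int(res.nit),
        theta=theta_hat,
        eta=eta_hat,
        boundary=on_bound,
    )
    if options.compute_se and converged and fix_eta is None:
        result.se = _standard_errors(
            model, het, prep, theta_hat, eta_hat, XU, gidx, G, on_bound=on_bound
        )
    return result


def _canonicalize_signs(model, theta: np.ndarray) -> np.ndarray:
    """Resolve the loading-sign indeterminacy: per factor, make the sum of
    baseline loadings positive (an exact likelihood-invariant reflection)."""
    names = model.theta.names
    if not any(n.startswith("lambda[") for n in names):
        return theta
    theta = theta.copy()
    q = getattr(model, "q", 0) or 0
    for f in range(1, q + 1):
        ssum = sum(
            theta[j]
            for j, n in enumerate(names)
            if n.startswith("lambda[") and "@" not in n and n.endswith(f",{f}]")
        )
        if ssum >= 0:
            continue
        for j, n in enumerate(names):
            base = n.split("@")[0]
            if base.startswith("lambda[") and base.endswith(f",{f}]"):
                theta[j] = -theta[j]
            elif base == f"kappa[{f}]":
                theta[j] = -theta[j]
            elif base.startswith("phi["):
                a, bnum = base[4:-1].split(",")
                a, bnum = int(a), int(bnum)
                if a != bnum and (a == f) != (bnum == f):
                    theta[j] = -theta[j]
    return theta


def _joint_gradient(model, het, prep, theta, eta, XU, gidx, G):
    T2 = het.build(eta)
    Oinv, logdets, const, ok = _omega_terms(T2, prep)
    if not ok:
        raise np.linalg.LinAlgError("non-PD total covariance at the optimum")
    group_masks = [gidx == g for g in range(G)]
    A, b, _ = _aggregates(Oinv, prep.y, group_masks)
    m0, J = model.moments_and_jac(theta, XU)
    resid_w = (A @ m0[:, :, None])[:, :, 0] - b
    grad_theta = 2.0 * (J * resid_w[:, :, None]).sum((0, 1))
    r = prep.y - m0[gidx]
    u = (Oinv @ r[:, :, None])[:, :, 0]
    grad_eta = het.grad_quadratic(eta, Oinv.sum(0) - u.T @ u)
    return np.concatenate([grad_theta, grad_eta])


def _standard_errors(model, het, prep, theta, eta, XU, gidx, G, on_bound=()):
    """SEs from the inverse observed information (numerical Hessian of -2LL
    via central differences of the analytic joint gradient).  Heterogeneity
    parameters pinned at a bound carry no curvature and are excluded: the
    remaining SEs are conditional on the boundary."""
    x0 = np.concatenate([theta, eta])
    nt = len(theta)
    n = x0.size

    def grad(x):
        return _joint_gradient(model, het, prep, x[:nt], x[nt:], XU, gidx, G)

    names = list(model.theta.names) + list(het.param_names)
    keep = np.array([nm not in on_bound for nm in names])
    H = np.zeros((n, n))
    for j in np.where(keep)[0]:
        h = 1e-5 * max(1.0, abs(x0[j]))
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (grad(xp) - grad(xm)) / (2 * h)
    H = (H + H.T) / 2

    def _try(mask):
        try:
            cov = 2.0 * np.linalg.inv(H[np.ix_(mask, mask)])
            diag = np.diag(cov)
            if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
                return None
            return dict(zip([nm for nm, k in zip(names, mask) if k], np.sqrt(diag)))
        except np.linalg.LinAlgError:
            return None

    out = _try(keep)
    if out is None:
        # degenerate heterogeneity curvature: report mean-structure SEs
        # conditional on the heterogeneity estimates
        theta_only = np.zeros(n, dtype=bool)
        theta_only[:nt] = True
        out = _try(theta_only & keep)
    return out


def fit(
    spec: CFASpec,
    het: HeterogeneitySpec | None,
    data,
    options: FitOptions | None = None,
    eta0: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    name: str = "cfa",
    fix_eta: np.ndarray | None = None,
) -> FitResult:
    """Fit a (moderated) CFA-with-means by marginal maximum likelihood.

    ``fix_eta`` holds the heterogeneity parameters fixed at the given values
    (e.g. near-zero for a fixed-effect analysis) and profiles only the mean
    structure."""
    prep = _as_prepared(data)
    if het is None:
        het = HeterogeneitySpec(p=prep.p)
    spec.check_identified()
    model = spec.compile()
    options = options or FitOptions()
    return _fit_core(
        model, het, prep, options, eta0=eta0, theta0=theta0, model_name=name, fix_eta=fix_eta
    )


def fit_saturated(
    het: HeterogeneitySpec | None,
    data,
    moderated: bool = False,
    moderators: list[str] | None = None,
    options: FitOptions | None = None,
    eta0: np.ndarray | None = None,
    fix_eta: np.ndarray | None = None,
) -> FitResult:
    """Fit the saturated means-and-covariances baseline (chi-square reference).

    With ``moderated=True`` every effect-size mean is additionally regressed
    on the moderators (all of them by default)."""
    prep = _as_prepared(data)
    if het is None:
        het = HeterogeneitySpec(p=prep.p)
    mods = (moderators if moderators is not None else sorted(prep.x)) if moderated else []
    model = SaturatedMeanModel(prep.p, mods)
    options = options or FitOptions()
    return _fit_core(
        model, het, prep, options, eta0=eta0, model_name="saturated", fix_eta=fix_eta
    )


def fit_invariance_ladder(
    base_spec: CFASpec,
    group_dummy: str,
    data,
    het: HeterogeneitySpec | None = None,
    options: FitOptions | None = None,
    partial_free_weak: tuple[str, ...] = (),
    partial_free_strong: tuple[str, ...] = (),
) -> dict[str, FitResult]:
    """Fit the moderated saturated baseline and the configural / weak /
    strong invariance models, warm-starting the heterogeneity parameters
    along the ladder."""
    from .cfa_model import build_invariance_model

    prep = _as_prepared(data)
    if het is None:
        het = HeterogeneitySpec(p=prep.p)
    options = options or FitOptions()
    out: dict[str, FitResult] = {}
    out["saturated"] = fit_saturated(
        het, prep, moderated=True, moderators=[group_dummy], options=options
    )
    eta_warm = out["saturated"].eta
    params_warm: dict = {}
    for level, pf in (
        ("configural", ()),
        ("weak", partial_free_weak),
        ("strong", partial_free_strong),
    ):
        spec = build_invariance_model(base_spec, level, group_dummy, partial_free=pf)
        model = spec.compile()
        theta0 = _data_driven_starts(model, prep)
        for j, nm in enumerate(model.theta.names):
            if nm in params_warm:
                theta0[j] = params_warm[nm]
        out[level] = fit(
            spec, het, prep, options=options, eta0=eta_warm, theta0=theta0, name=level
        )
        if out[level].converged:
            eta_warm = out[level].eta
            params_warm = out[level].params
    return out


def marginal_loglik(spec_or_model, theta, het: HeterogeneitySpec, eta, data) -> float:
    """Log-likelihood sum_i log N(y_i; m(theta, x_i), T^2 + V_i) at fixed
    parameter values (no optimization)."""
    prep = _as_prepared(data)
    model = spec_or_model.compile() if isinstance(spec_or_model, CFASpec) else spec_or_model
    T2 = het.build(np.asarray(eta, dtype=float))
    Oinv, logdets, const, ok = _omega_terms(T2, prep)
    if not ok:
        return -_PENALTY
    X = prep.moderator_matrix(model.moderators)
    XU, gidx = _unique_groups(X)
    m = model.moments(np.asarray(theta, dtype=float), XU)
    r = prep.y - m[gidx]
    quad = float(np.einsum("ki,kij,kj->", r, Oinv, r))
    return -0.5 * (const + float(logdets.sum()) + quad)


# ---------------------------------------------------------------------------
# model comparison statistics
# ---------------------------------------------------------------------------


def lrt(restricted: FitResult, general: FitResult, tol: float = 1e-6):
    """Chi-square difference test between nested fits on the same data.

    Returns (delta_chi2, delta_df, p).  A negative difference beyond
    tolerance indicates non-convergence of one of the fits and raises.
    """
    if restricted.k != general.k or restricted.N_total != general.N_total:
        raise ValueError("fits do not appear to be on the same data")
    ddf = restricted.df - general.df
    if ddf < 0:
        raise ValueError("restricted model has fewer degrees of freedom than the general one")
    delta = restricted.minus2LL - general.minus2LL
    if delta < -tol * max(1.0, abs(general.minus2LL)):
        raise ValueError(
            f"negative chi-square difference ({delta:.3g}): check convergence "
            f"of the general model"
        )
    delta = max(delta, 0.0)
    if ddf == 0:
        p = 1.0 if delta <= tol * max(1.0, abs(general.minus2LL)) else 0.0
    else:
        p = float(stats.chi2.sf(delta, ddf))
    return delta, ddf, p


def information_criteria(fit_result: FitResult) -> tuple[float, float]:
    """AIC = -2LL + 2 r and BIC = -2LL + r log(N), with r counting all free
    parameters including the heterogeneity ones and N the summed
    within-study sample size.  Likelihood constants are included
    consistently, so differences between fits on the same data are
    meaningful."""
    r = fit_result.n_free
    aic = fit_result.minus2LL + 2.0 * r
    bic = fit_result.minus2LL + r * np.log(fit_result.N_total)
    return float(aic), float(bic)


def rmsea(chi2: float, df: int, N_total: int) -> float:
    """Root-mean-square error of approximation,
    sqrt(max(chi2 - df, 0) / (df (N - 1))), with N the summed within-study
    sample size.  Undefined (NaN) at df = 0.  Other conventions exist in
    the MASEM literature; this one is flagged in all reports."""
    if df <= 0:
        warnings.warn("RMSEA undefined at df = 0", stacklevel=2)
        return float("nan")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (N_total - 1))))


def wald_test(fit_result: FitResult, parameter: str):
    """Wald z-test of one free parameter: (estimate, se, z, two-sided p)."""
    allp = {**fit_result.params, **fit_result.het_params}
    if parameter not in allp:
        raise ValueError(f"unknown parameter {parameter!r}")
    if not fit_result.se or parameter not in fit_result.se:
        raise ValueError(f"no standard error available for {parameter!r}")
    est = allp[parameter]
    se = fit_result.se[parameter]
    z = est / se
    return est, se, z, float(2 * stats.norm.sf(abs(z)))


def smd(mean_diff: float, phi_ref: float, phi_other: float) -> float:
    """Standardized latent mean difference: the raw difference divided by the
    pooled factor standard deviation sqrt((phi_ref + phi_other)/2)."""
    if phi_ref <= 0 or phi_other <= 0:
        raise ValueError("factor variances must be positive")
    return float(mean_diff / np.sqrt((phi_ref + phi_other) / 2.0))
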