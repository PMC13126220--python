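"""Confirmatory factor models with mean structures and parameter moderation.

A :class:`CFASpec` describes a CFA with mean structure,

    Sigma = Lambda Phi Lambda' + Psi          (model-implied covariances)
    mu    = tau + Lambda kappa                (model-implied means)

in which any free parameter may additionally be regressed on study-level
moderators ("regression approach"): a moderated parameter at moderator
vector x equals ``beta0 + sum_m beta1_m * x_m``.  With a 0/1 group dummy
this reproduces multigroup modeling; with continuous moderators it
generalizes it (moderated nonlinear factor analysis).

Measurement-invariance models across (groups of) studies are generated by
:func:`build_invariance_model`:

* configural — all free CFA parameters moderated; factor variances fixed
  at 1 and factor means fixed at 0 at every moderator value;
* weak — loading slopes removed (loadings invariant); factor-variance
  slopes added (baseline fixed at 1);
* strong — additionally intercept slopes removed; factor-mean slopes
  added (baseline fixed at 0), so each factor-mean slope estimates the
  latent mean difference between groups.

``partial_free`` exempts named loadings (weak) or loadings/intercepts
(strong) from invariance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .summary_data import vech_indices

__all__ = [
    "Free",
    "CFASpec",
    "CompiledModel",
    "ParameterVector",
    "InvarianceLevel",
    "implied_moments",
    "build_invariance_model",
    "count_df",
]

_CSTEP = 1e-100  # complex-step size; derivative = Im(f(x + i h))/h, exact here


@dataclass(frozen=True)
class Free:
    """A free parameter with a starting value."""

    start: float = 0.0


ParamSpec = "float | Free"


@dataclass
class InvarianceLevel:
    """One of configural / weak / strong, with optional partial exemptions."""

    level: str
    partial_free: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.level not in ("configural", "weak", "strong"):
            raise ValueError(f"unknown invariance level {self.level!r}")
        self.partial_free = tuple(self.partial_free)
        for name in self.partial_free:
            is_loading = name.startswith("lambda[")
            is_intercept = name.startswith("tau[")
            if self.level == "configural":
                raise ValueError("partial_free has no meaning under configural invariance")
            if self.level == "weak" and not is_loading:
                raise ValueError(f"under weak invariance partial_free must name loadings: {name}")
            if self.level == "strong" and not (is_loading or is_intercept):
                raise ValueError(
                    f"under strong invariance partial_free must name loadings or intercepts: {name}"
                )


@dataclass
class CFASpec:
    """Pattern specification of a (possibly moderated) CFA with means.

    Entries are either a fixed ``float`` or :class:`Free`.  ``loadings`` is
    keyed by ``(variable, factor)`` — absent pairs are fixed at 0.  ``phi``
    is keyed by ``(factor_a, factor_b)`` (symmetric; store one triangle),
    ``psi`` and ``tau`` by variable, ``kappa`` by factor.  ``moderation``
    maps a canonical parameter name (e.g. ``"lambda[2,1]"``) to
    ``{moderator: Free(...) or fixed float}`` slope entries.
    """

    var_names: list[str]
    factor_names: list[str]
    loadings: dict = field(default_factory=dict)
    phi: dict = field(default_factory=dict)
    psi: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)
    kappa: dict = field(default_factory=dict)
    moderation: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_loadings(
        cls,
        var_names: list[str],
        factors: dict[str, list[str]],
        loading_start: float = 0.5,
        psi_start: float = 0.25,
        fix_residual_zero: tuple[str, ...] = (),
    ) -> "CFASpec":
        """Reference configuration: free loadings per the pattern, factor
        variances fixed at 1, factor means fixed at 0, free factor
        covariances, free residual variances (fixed 0 for single-indicator
        factors listed in ``fix_residual_zero``) and free intercepts."""
        factor_names = list(factors)
        spec = cls(var_names=list(var_names), factor_names=factor_names)
        for f, indicators in factors.items():
            for v in indicators:
                if v not in var_names:
                    raise ValueError(f"unknown indicator {v!r}")
                spec.loadings[(v, f)] = Free(loading_start)
        for a_i, fa in enumerate(factor_names):
            spec.phi[(fa, fa)] = 1.0
            for fb in factor_names[a_i + 1 :]:
                spec.phi[(fa, fb)] = Free(0.0)
            spec.kappa[fa] = 0.0
        for v in var_names:
            spec.psi[v] = 0.0 if v in fix_residual_zero else Free(psi_start)
            spec.tau[v] = Free(0.0)
        return spec

    # -- bookkeeping --------------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.var_names)

    @property
    def q(self) -> int:
        return len(self.factor_names)

    @property
    def d(self) -> int:
        return self.p * (self.p + 1) // 2 + self.p

    def _vi(self, v: str) -> int:
        return self.var_names.index(v)

    def _fi(self, f: str) -> int:
        return self.factor_names.index(f)

    def param_name(self, matrix: str, key) -> str:
        """Canonical 1-based name, ``matrix[row,col]`` or ``matrix[row]``."""
        if matrix == "lambda":
            v, f = key
            return f"lambda[{self._vi(v) + 1},{self._fi(f) + 1}]"
        if matrix == "phi":
            a, b = sorted((self._fi(key[0]), self._fi(key[1])), reverse=True)
            return f"phi[{a + 1},{b + 1}]"
        if matrix == "psi":
            i = self._vi(key) + 1
            return f"psi[{i},{i}]"
        if matrix == "tau":
            return f"tau[{self._vi(key) + 1}]"
        if matrix == "kappa":
            return f"kappa[{self._fi(key) + 1}]"
        raise ValueError(matrix)

    def _entries(self):
        """Yield (matrix, key, spec_entry, canonical_name) for every entry."""
        for key, v in self.loadings.items():
            yield "lambda", key, v, self.param_name("lambda", key)
        for key, v in self.phi.items():
            yield "phi", key, v, self.param_name("phi", key)
        for key, v in self.psi.items():
            yield "psi", key, v, self.param_name("psi", key)
        for key, v in self.tau.items():
            yield "tau", key, v, self.param_name("tau", key)
        for key, v in self.kappa.items():
            yield "kappa", key, v, self.param_name("kappa", key)

    @property
    def moderator_names(self) -> list[str]:
        names: list[str] = []
        for slopes in self.moderation.values():
            for m in slopes:
                if m not in names:
                    names.append(m)
        return names

    @property
    def n_free(self) -> int:
        n = sum(1 for *_, v, _name in self._entries() if isinstance(v, Free))
        n += sum(
            1
            for slopes in self.moderation.values()
            for s in slopes.values()
            if isinstance(s, Free)
        )
        return n

    def check_identified(self) -> None:
        """Every factor needs a scale (fixed loading or fixed variance) and an
        origin (fixed intercept among its indicators or fixed mean) in the
        reference configuration."""
        for f in self.factor_names:
            indicators = [v for (v, ff) in self.loadings if ff == f]
            has_scale = not isinstance(self.phi.get((f, f), 0.0), Free) or any(
                not isinstance(self.loadings[(v, f)], Free) for v in indicators
            )
            has_origin = not isinstance(self.kappa.get(f, 0.0), Free) or any(
                not isinstance(self.tau.get(v, Free()), Free) for v in indicators
            )
            if not has_scale:
                raise ValueError(f"factor {f!r} has no scale (fix a loading or its variance)")
            if not has_origin:
                raise ValueError(f"factor {f!r} has no origin (fix an intercept or its mean)")

    def compile(self) -> "CompiledModel":
        return CompiledModel(self)


@dataclass
class ParameterVector:
    """Ordered free parameters (baselines then their moderator slopes)."""

    names: list[str]
    start: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


class CompiledModel:
    """Index-compiled moment map theta, x -> [vech(Sigma); mu].

    Supports batched evaluation over leading axes of ``theta`` and over a
    grid of moderator vectors ``X`` (G x n_moderators), and complex-step
    Jacobians (the map is polynomial in theta, so the complex step is exact
    to machine precision).
    """

    def __init__(self, spec: CFASpec):
        self.spec = spec
        p, q = spec.p, spec.q
        self.p, self.q = p, q
        self.d = spec.d
        self.moderators = spec.moderator_names
        self.vr, self.vc = vech_indices(p)

        names: list[str] = []
        starts: list[float] = []
        # per-matrix: base array, baseline assignments, slope additions
        self._base = {
            "lambda": np.zeros((p, q)),
            "phi": np.zeros((q, q)),
            "psi": np.zeros(p),
            "tau": np.zeros(p),
            "kappa": np.zeros(q),
        }
        self._assign: dict[str, list] = {m: [] for m in self._base}  # (pos..., theta_idx)
        self._slopes: dict[str, list] = {m: [] for m in self._base}  # (pos..., theta_idx, mod_idx)
        mod_index = {m: i for i, m in enumerate(self.moderators)}

        def positions(matrix, key):
            if matrix == "lambda":
                return [(spec._vi(key[0]), spec._fi(key[1]))]
            if matrix == "phi":
                a, b = spec._fi(key[0]), spec._fi(key[1])
                return [(a, b)] if a == b else [(a, b), (b, a)]
            if matrix == "psi":
                return [(spec._vi(key),)]
            if matrix == "tau":
                return [(spec._vi(key),)]
            return [(spec._fi(key),)]

        seen = set()
        for matrix, key, entry, name in spec._entries():
            if name in seen:
                raise ValueError(f"duplicate parameter entry {name}")
            seen.add(name)
            pos = positions(matrix, key)
            if isinstance(entry, Free):
                k = len(names)
                names.append(name)
                starts.append(entry.start)
                for pp in pos:
                    self._assign[matrix].append((pp, k))
            else:
                for pp in pos:
                    self._base[matrix][pp] = float(entry)
            for mod, sl in spec.moderation.get(name, {}).items():
                if isinstance(sl, Free):
                    k = len(names)
                    names.append(f"{name}@{mod}")
                    starts.append(sl.start)
                    for pp in pos:
                        self._slopes[matrix].append((pp, k, mod_index[mod]))
                else:
                    # fixed nonzero slope: folded in as a moderator-dependent base
                    for pp in pos:
                        self._slopes[matrix].append((pp, float(sl), mod_index[mod]))
        self.theta = ParameterVector(names=names, start=np.array(starts, dtype=float))
        self.t = len(names)

        # vectorized index arrays for fast batched assembly
        self._vec = {}
        for matrix in self._base:
            assign = self._assign[matrix]
            a_pos = tuple(
                np.array([pp[ax] for pp, _ in assign], dtype=int)
                for ax in range(self._base[matrix].ndim)
            )
            a_tidx = np.array([k for _, k in assign], dtype=int)
            free_sl = [(pp, k, mi) for pp, k, mi in self._slopes[matrix] if isinstance(k, int)]
            fix_sl = [(pp, k, mi) for pp, k, mi in self._slopes[matrix] if not isinstance(k, int)]
            s_pos = tuple(
                np.array([pp[ax] for pp, _, _ in free_sl], dtype=int)
                for ax in range(self._base[matrix].ndim)
            )
            s_tidx = np.array([k for _, k, _ in free_sl], dtype=int)
            s_midx = np.array([mi for _, _, mi in free_sl], dtype=int)
            # fancy-index += drops duplicate positions; fall back to a loop then
            pos_list = [pp for pp, _, _ in free_sl]
            s_dup = len(pos_list) != len(set(pos_list))
            self._vec[matrix] = (a_pos, a_tidx, s_pos, s_tidx, s_midx, s_dup, fix_sl)

    # -- evaluation ---------------------------------------------------------

    def _matrices(self, theta: np.ndarray, X: np.ndarray):
        theta = np.asarray(theta)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.moderators):
            raise ValueError(
                f"expected {len(self.moderators)} moderator values per row, got {X.shape[1]}"
            )
        G = X.shape[0]
        lead = theta.shape[:-1]
        out = {}
        for matrix, base in self._base.items():
            A = np.zeros(lead + (G,) + base.shape, dtype=theta.dtype)
            A[...] = base
            a_pos, a_tidx, s_pos, s_tidx, s_midx, s_dup, fix_sl = self._vec[matrix]
            if a_tidx.size:
                A[(...,) + (slice(None),) + a_pos] = theta[..., a_tidx][..., None, :]
            if s_tidx.size:
                if s_dup:
                    for pp, k, mi in self._slopes[matrix]:
                        if isinstance(k, int):
                            A[(...,) + (slice(None),) + pp] += theta[..., k][..., None] * X[:, mi]
                else:
                    A[(...,) + (slice(None),) + s_pos] += (
                        theta[..., s_tidx][..., None, :] * X[:, s_midx]
                    )
            for pp, k, mi in fix_sl:
                A[(...,) + (slice(None),) + pp] += k * X[:, mi]
            out[matrix] = A
        return out, G

    def moments(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Model-implied ``[vech(Sigma); mu]``, shape ``theta.lead + (G, d)``."""
        mats, G = self._matrices(theta, X)
        lam, phi, psi, tau, kappa = (
            mats["lambda"],
            mats["phi"],
            mats["psi"],
            mats["tau"],
            mats["kappa"],
        )
        sigma = lam @ phi @ np.swapaxes(lam, -1, -2)
        idx = np.arange(self.p)
        sigma[..., idx, idx] += psi
        mu = tau + (lam @ kappa[..., None])[..., 0]
        return np.concatenate([sigma[..., self.vr, self.vc], mu], axis=-1)

    def moments_and_jac(self, theta: np.ndarray, X: np.ndarray):
        """Value (G, d) and Jacobian (G, d, t) at a single theta vector."""
        theta = np.asarray(theta, dtype=float)
        if self.t == 0:
            m0 = self.moments(theta, X)
            return m0, np.zeros(m0.shape + (0,))
        th = theta[None, :] + 1j * _CSTEP * np.eye(self.t)
        mc = self.moments(th, X)  # (t, G, d) complex
        return mc[0].real, np.moveaxis(mc.imag / _CSTEP, 0, -1)

    def moderator_matrix(self, records) -> np.ndarray:
        """Extract the (k, n_moderators) matrix from study records."""
        rows = []
        for r in records:
            missing = [m for m in self.moderators if m not in r.moderators]
            if missing:
                raise ValueError(f"study {r.study_id} lacks moderator value(s) {missing}")
            rows.append([r.moderators[m] for m in self.moderators])
        return np.array(rows, dtype=float).reshape(len(rows), len(self.moderators))


def implied_moments(
    spec: CFASpec, theta: np.ndarray | None = None, x: dict[str, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied (Sigma, mu) at parameter vector ``theta`` and moderator
    values ``x`` (name -> value).  ``theta=None`` uses the starting values."""
    model = spec.compile()
    if theta is None:
        theta = model.theta.start
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.t,):
        raise ValueError(f"theta has length {theta.shape}, expected ({model.t},)")
    x = x or {}
    xv = np.array([[_require_mod(x, m) for m in model.moderators]])
    m = model.moments(theta, xv)[0]
    ns = spec.p * (spec.p + 1) // 2
    from .summary_data import unvech

    return unvech(m[:ns]), m[ns:]


def _require_mod(x: dict[str, float], name: str) -> float:
    if name not in x:
        raise ValueError(f"missing moderator value for {name!r}")
    return float(x[name])


def build_invariance_model(
    spec: CFASpec,
    level: InvarianceLevel | str,
    group_dummy: str,
    partial_free: tuple[str, ...] = (),
) -> CFASpec:
    """Derive the configural / weak / strong invariance model from a
    reference-configuration spec by moderating parameters on ``group_dummy``.

    The input spec must be identified in the reference configuration
    (typically factor variances fixed at 1 and factor means fixed at 0).
    The same mechanics apply to a continuous moderator.
    """
    if isinstance(level, str):
        level = InvarianceLevel(level, partial_free)
    elif partial_free:
        level = InvarianceLevel(level.level, tuple(level.partial_free) + tuple(partial_free))
    spec.check_identified()
    out = copy.deepcopy(spec)
    out.moderation = copy.deepcopy(spec.moderation)
    exempt = set(level.partial_free)

    def add_slope(name: str) -> None:
        out.moderation.setdefault(name, {})[group_dummy] = Free(0.0)

    known = {name for _, _, _, name in spec._entries()}
    for name in exempt:
        if name not in known:
            raise ValueError(f"partial_free names unknown parameter {name}")

    for matrix, key, entry, name in spec._entries():
        free = isinstance(entry, Free)
        if matrix == "lambda":
            if free and (level.level == "configural" or name in exempt):
                add_slope(name)
        elif matrix == "phi":
            diag = key[0] == key[1]
            if level.level == "configural":
                if free:
                    add_slope(name)
                # fixed factor variances stay fixed at every moderator value
            else:
                # weak/strong: fixed factor variances get a free slope so the
                # non-reference group's variance is estimated
                if free or diag:
                    add_slope(name)
        elif matrix in ("psi",):
            if free:
                add_slope(name)
        elif matrix == "tau":
            if free and (level.level in ("configural", "weak") or name in exempt):
                add_slope(name)
        elif matrix == "kappa":
            if level.level == "strong":
                # fixed factor means get a free slope: the latent mean difference
                add_slope(name)
            elif free:
                add_slope(name)
    return out


def count_df(spec: CFASpec, p: int | None = None, n_groups: int = 2) -> int:
    """Residual degrees of freedom versus the moderated saturated model.

    df = n_groups * (p(p+1)/2 + p) - (free baseline + slope parameters of the
    mean structure); heterogeneity parameters are shared with the saturated
    baseline and excluded from the count.  For a design with ``n_groups``
    dummy-coded groups the saturated moderated model has ``n_groups`` free
    moments per effect size.
    """
    spec.check_identified()
    if p is None:
        p = spec.p
    if p != spec.p:
        raise ValueError(f"spec has p={spec.p}, got p={p}")
    d = p * (p + 1) // 2 + p
    return n_groups * d - spec.n_free
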