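"""Study-level summary statistics: containers, vectorization, sampling covariances.

The unit of analysis is one primary study reporting a sample covariance
matrix ``S`` (p x p), a vector of sample means ``ybar`` (length p), the
within-study sample size ``n``, and study-level moderator values.  The
meta-analytic machinery works on the stacked effect-size vector

    y_i = [vech(S_i); ybar_i]

of length d = p(p+1)/2 + p, together with its normal-theory within-study
sampling covariance matrix V_i, which is treated as known.

The vech ordering is column-major over the lower triangle including the
diagonal: (1,1), (2,1), ..., (p,1), (2,2), (3,2), ...  Every module in the
package uses this ordering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "EffectVector",
    "SamplingCovariance",
    "vech",
    "unvech",
    "vech_indices",
    "vech_labels",
    "effect_vector",
    "compute_sampling_covariance",
    "read_studies",
    "write_studies",
]

_SYM_TOL = 1e-8
_PSD_TOL = 1e-8


def vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the lower triangle in column-major order.

    Returns arrays ``(rows, cols)`` of length p(p+1)/2 such that
    ``M[rows, cols]`` is vech(M).
    """
    cols, rows = np.triu_indices(p)  # triu row-major == tril column-major, transposed
    return rows, cols


def vech_labels(names: list[str]) -> list[str]:
    """Labels ``cov(a,b)`` (a below-or-on the diagonal) for vech positions."""
    rows, cols = vech_indices(len(names))
    return [f"cov({names[i]},{names[j]})" for i, j in zip(rows, cols)]


def vech(M: np.ndarray, tol: float = _SYM_TOL) -> np.ndarray:
    """Half-vectorization: stack the lower triangle (incl. diagonal) of ``M``.

    ``M`` must be square and symmetric within ``tol`` (absolute, relative to
    the largest entry).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"vech expects a square matrix, got shape {M.shape}")
    scale = max(1.0, float(np.max(np.abs(M))) if M.size else 1.0)
    if np.max(np.abs(M - M.T), initial=0.0) > tol * scale:
        raise ValueError("vech expects a symmetric matrix (asymmetry beyond tolerance)")
    rows, cols = vech_indices(M.shape[0])
    return M[rows, cols]


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech` under the fixed column-major ordering."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("unvech expects a 1-d vector")
    # p(p+1)/2 = len  =>  p = (sqrt(8 len + 1) - 1)/2 must be integral
    p = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    if p * (p + 1) // 2 != v.size:
        raise ValueError(f"length {v.size} is not a triangular number")
    M = np.zeros((p, p))
    rows, cols = vech_indices(p)
    M[rows, cols] = v
    M[cols, rows] = v
    return M


@dataclass
class StudyRecord:
    """Summary statistics of one primary study."""

    study_id: str
    n: int
    S: np.ndarray
    ybar: np.ndarray
    moderators: dict[str, float] = field(default_factory=dict)
    observed_mask: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.ybar = np.asarray(self.ybar, dtype=float)
        p = self.p
        if self.S.shape != (p, p):
            raise ValueError(
                f"study {self.study_id}: S has shape {self.S.shape}, expected ({p},{p})"
            )
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.ybar) & ~np.isnan(np.diag(self.S))
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != (p,):
            raise ValueError(f"study {self.study_id}: observed_mask length mismatch")
        if self.n < 2:
            raise ValueError(f"study {self.study_id}: n must be >= 2, got {self.n}")
        self.validate()

    @property
    def p(self) -> int:
        return self.ybar.shape[0]

    def validate(self) -> list[str]:
        """Check symmetry and positive semidefiniteness on the observed submatrix.

        Violations are recorded in ``flags`` (and returned), not raised, so a
        dataset reader can keep the healthy records.
        """
        self.flags = []
        obs = self.observed_mask
        Sobs = self.S[np.ix_(obs, obs)]
        scale = max(1.0, float(np.max(np.abs(Sobs))) if Sobs.size else 1.0)
        if np.max(np.abs(Sobs - Sobs.T), initial=0.0) > _SYM_TOL * scale:
            self.flags.append("covariance matrix not symmetric")
        elif Sobs.size:
            mineig = float(np.linalg.eigvalsh((Sobs + Sobs.T) / 2)[0])
            if mineig < -_PSD_TOL * scale:
                self.flags.append("covariance matrix not positive semidefinite")
            elif mineig <= _PSD_TOL * scale:
                self.flags.append("covariance matrix singular (flagged for exclusion)")
        if np.any(np.isnan(self.ybar[obs])):
            self.flags.append("missing means among observed variables")
        return self.flags

    @property
    def ok(self) -> bool:
        return not self.flags


@dataclass
class EffectVector:
    """Stacked effect sizes ``[vech(S); ybar]`` with an index map."""

    values: np.ndarray
    index_map: list[tuple[str, int, int]]  # ("cov", i, j) with i >= j, or ("mean", i, i)
    present: np.ndarray

    @property
    def d(self) -> int:
        return self.values.shape[0]


def effect_vector(record: StudyRecord) -> EffectVector:
    """Stack a study's summary statistics into its effect-size vector."""
    p = record.p
    rows, cols = vech_indices(p)
    S = np.where(np.isnan(record.S), 0.0, record.S)
    values = np.concatenate([((S + S.T) / 2)[rows, cols], np.nan_to_num(record.ybar)])
    index_map = [("cov", int(i), int(j)) for i, j in zip(rows, cols)]
    index_map += [("mean", i, i) for i in range(p)]
    obs = record.observed_mask
    present = np.concatenate([obs[rows] & obs[cols], obs])
    return EffectVector(values=values, index_map=index_map, present=present)


@dataclass
class SamplingCovariance:
    """Within-study sampling covariance V_i of ``[vech(S); ybar]``.

    Under multivariate normality with the unbiased covariance estimator,

        Cov(s_ij, s_kl) = (S_ik S_jl + S_il S_jk) / (n - 1)
        Cov(ybar)       = S / n
        Cov(s_ij, ybar) = 0   (third central moments of the normal vanish).
    """

    V: np.ndarray
    present: np.ndarray
    valid: bool = True

    @property
    def _split(self) -> int:
        return self.V.shape[0] - _p_from_d(self.V.shape[0])

    @property
    def cov_block(self) -> np.ndarray:
        return self.V[: self._split, : self._split]

    @property
    def mean_block(self) -> np.ndarray:
        return self.V[self._split :, self._split :]

    @property
    def cross_block(self) -> np.ndarray:
        return self.V[: self._split, self._split :]


def _p_from_d(d: int) -> int:
    # d = p(p+1)/2 + p  =>  p = (sqrt(8d+9) - 3)/2
    p = int(round((np.sqrt(8 * d + 9) - 3) / 2))
    assert p * (p + 1) // 2 + p == d, d
    return p


def compute_sampling_covariance(
    S: np.ndarray, n: int, observed_mask: np.ndarray | None = None
) -> SamplingCovariance:
    """Normal-theory sampling covariance of ``[vech(S); ybar]``.

    The study's own observed ``S`` is plugged in (the "treated as known"
    convention).  Rows/columns for unobserved variables are flagged absent
    in ``present``; a singular observed ``S`` marks the result invalid so
    the study can be excluded (no pseudo-inverse fallback is attempted).
    """
    S = np.asarray(S, dtype=float)
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    p = S.shape[0]
    if S.shape != (p, p):
        raise ValueError("S must be square")
    if observed_mask is None:
        observed_mask = ~np.isnan(np.diag(S))
    observed_mask = np.asarray(observed_mask, dtype=bool)

    rows, cols = vech_indices(p)
    Sz = np.where(np.isnan(S), 0.0, (S + np.where(np.isnan(S.T), S, S.T)) / 2)
    # Cov(s_ab, s_cd) = (S_ac S_bd + S_ad S_bc)/(n-1), vectorized over vech pairs
    a, b = rows[:, None], cols[:, None]
    c, d_ = rows[None, :], cols[None, :]
    cov_block = (Sz[a, c] * Sz[b, d_] + Sz[a, d_] * Sz[b, c]) / (n - 1)
    mean_block = Sz / n

    dtot = rows.size + p
    V = np.zeros((dtot, dtot))
    V[: rows.size, : rows.size] = cov_block
    V[rows.size :, rows.size :] = mean_block
    present = np.concatenate([observed_mask[rows] & observed_mask[cols], observed_mask])

    valid = True
    Sobs = Sz[np.ix_(observed_mask, observed_mask)]
    if Sobs.size:
        scale = max(1.0, float(np.max(np.abs(Sobs))))
        if np.linalg.eigvalsh((Sobs + Sobs.T) / 2)[0] <= _PSD_TOL * scale:
            warnings.warn(
                "singular sample covariance matrix: study flagged for exclusion",
                stacklevel=2,
            )
            valid = False
    return SamplingCovariance(V=V, present=present, valid=valid)


# ---------------------------------------------------------------------------
# I/O: a small JSON/YAML sidecar declares variables, moderators and the
# component tables; studies are stored as plain delimited text.
# ---------------------------------------------------------------------------


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def read_studies(
    path: str | Path, format: str | None = None, fail_fast: bool = False
) -> list[StudyRecord]:
    """Read study records from a sidecar-described dataset.

    ``path`` points at a JSON or YAML sidecar with keys ``variables``,
    ``moderators``, ``format`` ("long" or "wide") and file references
    (relative to the sidecar): ``studies`` (study_id, n, moderator columns),
    plus either ``covariances`` (study_id, row, col, cov) and ``means``
    (study_id, variable, mean) in long format, or vech/mean columns inside
    the studies table in wide format.

    Records failing validation are flagged (kept) unless ``fail_fast``.
    """
    path = Path(path)
    meta = _load_sidecar(path)
    variables: list[str] = list(meta["variables"])
    moderators: list[str] = list(meta.get("moderators", []))
    fmt = format or meta.get("format", "long")
    base = path.parent
    p = len(variables)
    vidx = {v: i for i, v in enumerate(variables)}

    studies = pd.read_csv(base / meta["studies"])
    missing_cols = {"study_id", "n"} - set(studies.columns)
    if missing_cols:
        raise ValueError(f"studies table lacks columns {sorted(missing_cols)}")
    unknown = set(moderators) - set(studies.columns)
    if unknown:
        raise ValueError(f"moderator columns not in studies table: {sorted(unknown)}")

    records: list[StudyRecord] = []
    if fmt == "long":
        covs = pd.read_csv(base / meta["covariances"])
        means = pd.read_csv(base / meta["means"])
        cov_groups = dict(tuple(covs.groupby("study_id", sort=False)))
        mean_groups = dict(tuple(means.groupby("study_id", sort=False)))
        for _, row in studies.iterrows():
            sid = str(row["study_id"])
            S = np.full((p, p), np.nan)
            for _, c in cov_groups.get(sid, pd.DataFrame(columns=covs.columns)).iterrows():
                i, j = vidx[str(c["row"])], vidx[str(c["col"])]
                S[i, j] = S[j, i] = float(c["cov"])
            ybar = np.full(p, np.nan)
            for _, m in mean_groups.get(sid, pd.DataFrame(columns=means.columns)).iterrows():
                ybar[vidx[str(m["variable"])]] = float(m["mean"])
            records.append(_make_record(sid, row, S, ybar, moderators, fail_fast))
    elif fmt == "wide":
        rows_i, cols_i = vech_indices(p)
        for _, row in studies.iterrows():
            sid = str(row["study_id"])
            S = np.full((p, p), np.nan)
            for i, j in zip(rows_i, cols_i):
                col = f"cov_{variables[i]}_{variables[j]}"
                if col in studies.columns:
                    S[i, j] = S[j, i] = float(row[col])
            ybar = np.array(
                [
                    float(row[f"mean_{v}"]) if f"mean_{v}" in studies.columns else np.nan
                    for v in variables
                ]
            )
            records.append(_make_record(sid, row, S, ybar, moderators, fail_fast))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    n_flagged = sum(not r.ok for r in records)
    if n_flagged:
        warnings.warn(
            f"read {len(records)} studies, {n_flagged} flagged by validation",
            stacklevel=2,
        )
    return records


def _make_record(sid, row, S, ybar, moderators, fail_fast) -> StudyRecord:
    rec = StudyRecord(
        study_id=sid,
        n=int(row["n"]),
        S=S,
        ybar=ybar,
        moderators={m: float(row[m]) for m in moderators},
    )
    if fail_fast and not rec.ok:
        raise ValueError(f"study {sid}: " + "; ".join(rec.flags))
    return rec


def write_studies(
    records: list[StudyRecord],
    path: str | Path,
    variables: list[str] | None = None,
    format: str = "long",
) -> None:
    """Write records as a sidecar + delimited tables (inverse of read_studies)."""
    if format != "long":
        raise ValueError("only the long format is written")
    path = Path(path)
    base = path.parent
    base.mkdir(parents=True, exist_ok=True)
    p = records[0].p
    if variables is None:
        variables = [f"y{i + 1}" for i in range(p)]
    moderators = sorted(records[0].moderators)
    stem = path.stem

    studies_rows, cov_rows, mean_rows = [], [], []
    vr, vc = vech_indices(p)
    for rec in records:
        studies_rows.append(
            {"study_id": rec.study_id, "n": rec.n, **{m: rec.moderators[m] for m in moderators}}
        )
        obs = rec.observed_mask
        for i, j in zip(vr, vc):
            if obs[i] and obs[j] and not np.isnan(rec.S[i, j]):
                cov_rows.append(
                    {
                        "study_id": rec.study_id,
                        "row": variables[i],
                        "col": variables[j],
                        "cov": rec.S[i, j],
                    }
                )
        for i in range(p):
            if obs[i] and not np.isnan(rec.ybar[i]):
                mean_rows.append(
                    {"study_id": rec.study_id, "variable": variables[i], "mean": rec.ybar[i]}
                )

    pd.DataFrame(studies_rows).to_csv(base / f"{stem}_studies.csv", index=False)
    pd.DataFrame(cov_rows).to_csv(base / f"{stem}_covariances.csv", index=False)
    pd.DataFrame(mean_rows).to_csv(base / f"{stem}_means.csv", index=False)
    sidecar = {
        "variables": variables,
        "moderators": moderators,
        "format": "long",
        "studies": f"{stem}_studies.csv",
        "covariances": f"{stem}_covariances.csv",
        "means": f"{stem}_means.csv",
    }
    path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")


def dataset_summary(records: list[StudyRecord]) -> pd.DataFrame:
    """Validated dataset summary: one row per study with n, flags, moderators."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "n": r.n,
                "p_observed": int(r.observed_mask.sum()),
                "ok": r.ok,
                "flags": "; ".join(r.flags),
                **r.moderators,
            }
        )
    return pd.DataFrame(rows)
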