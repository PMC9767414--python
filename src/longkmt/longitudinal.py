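"""Longitudinal phenotype data and null-model fits.

The null model of every score test here contains no genetic term.  For
longitudinal data it is the linear mixed model with a random intercept and
a random time slope per subject,

    y = X beta + Z b + eps,   b_i ~ N(0, D),  eps ~ N(0, sigma_eps^2 I),

fitted by REML; the marginal covariance ``Sigma0 = Z D Z^T + sigma_eps^2 I``
(block diagonal by subject, assembled over observed rows only) feeds the
score statistic.  Missing records are simply absent rows — valid under a
missing-at-random mechanism, no imputation is performed.

For a two-time-point pre/post design an ANCOVA null is also provided:
ordinary least squares of the follow-up measurement on covariates plus the
baseline measurement, with ``Sigma0 = sigma_eps^2 I`` at the subject level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import RemlResult, reml_fit

__all__ = [
    "LongitudinalDataset",
    "NullModelFit",
    "fit_null_lmm",
    "fit_ancova_null",
]


@dataclass
class LongitudinalDataset:
    """Long-format phenotype table.

    ``table`` columns: ``subject_id``, ``time`` (integer index 0..m-1),
    ``y``, then covariate columns.  Rows with missing ``y`` are treated as
    unobserved and dropped from fits.
    """

    table: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        required = {"subject_id", "time", "y"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        obs = self.observed()
        if obs.duplicated(["subject_id", "time"]).any():
            raise ValueError("duplicate (subject, time) records")
        t = obs["time"].to_numpy()
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("time must be a nonnegative integer index")
        if obs["subject_id"].nunique() == 0:
            raise ValueError("no observed records")
        for c in self.covariates:
            if c not in self.table.columns:
                raise ValueError(f"covariate column {c!r} not in table")

    def observed(self) -> pd.DataFrame:
        return self.table[self.table["y"].notna()]

    @property
    def n_subjects(self) -> int:
        return self.observed()["subject_id"].nunique()

    @property
    def n_timepoints(self) -> int:
        return int(self.observed()["time"].max()) + 1

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(subject codes, time, y, X) over observed rows.

        X columns: intercept, covariates..., time.
        """
        obs = self.observed()
        subj, _ = pd.factorize(obs["subject_id"])
        t = obs["time"].to_numpy(dtype=float)
        y = obs["y"].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(obs))]
            + [obs[c].to_numpy(dtype=float) for c in self.covariates]
            + [t]
        )
        return subj, t, y, X


@dataclass
class NullModelFit:
    """Null-model estimates and marginal covariance structure.

    ``kind`` is "lmm" (longitudinal REML fit) or "ancova" (subject-level
    OLS, ``D`` zero, ``Sigma0 = sigma_eps2 * I``).
    """

    kind: str
    beta0: np.ndarray
    D0: np.ndarray
    sigma_eps2: float
    X: np.ndarray
    residuals: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    n_subjects: int
    n_obs: int
    subject: np.ndarray
    time: np.ndarray
    _reml: RemlResult | None = field(default=None, repr=False)

    def apply_sigma_inv(self, arr: np.ndarray) -> np.ndarray:
        """Apply ``Sigma0^{-1}`` through per-subject block solves."""
        if self.kind == "ancova":
            return np.asarray(arr, dtype=float) / self.sigma_eps2
        return self._reml.apply_sigma_inv(arr)

    def sigma0_dense(self) -> np.ndarray:
        if self.kind == "ancova":
            return self.sigma_eps2 * np.eye(self.n_obs)
        return self._reml.sigma0_dense()


def fit_null_lmm(dataset: LongitudinalDataset) -> NullModelFit:
    """REML fit of the random intercept + slope null model.

    Refuses single-time-point data (use :func:`fit_ancova_null` or a plain
    cross-sectional model); a boundary D (singular random-effect covariance)
    is retained and flagged, not rejected.
    """
    subj, t, y, X = dataset.design()
    res = reml_fit(subj, t, y, X)
    resid = y - X @ res.beta
    return NullModelFit(
        kind="lmm",
        beta0=res.beta,
        D0=res.D,
        sigma_eps2=res.sigma_eps2,
        X=X,
        residuals=resid,
        loglik=res.loglik,
        converged=res.converged,
        boundary=res.boundary,
        n_subjects=res.n_subjects,
        n_obs=res.n_obs,
        subject=subj,
        time=t,
        _reml=res,
    )


def fit_ancova_null(dataset: LongitudinalDataset) -> NullModelFit:
    """OLS null for a two-time-point design: ``y(1) ~ covariates + y(0)``.

    Only subjects observed at both time points enter; ``Sigma0`` is
    ``sigma_eps2 * I`` at the subject level.
    """
    obs = dataset.observed()
    times = sorted(obs["time"].unique())
    if len(times) != 2:
        raise ValueError(
            f"ANCOVA needs exactly 2 time points, found {len(times)}"
        )
    t0, t1 = times
    wide = obs.pivot(index="subject_id", columns="time", values="y")
    complete = wide.dropna()
    base = obs[obs["time"] == t0].set_index("subject_id").loc[complete.index]
    y1 = complete[t1].to_numpy(dtype=float)
    y0 = complete[t0].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(complete))]
        + [base[c].to_numpy(dtype=float) for c in dataset.covariates]
        + [y0]
    )
    beta, _, rank, _ = np.linalg.lstsq(X, y1, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("ANCOVA design matrix is rank deficient")
    resid = y1 - X @ beta
    dof = max(len(y1) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    n = len(y1)
    loglik = -0.5 * n * (np.log(2 * np.pi * max(s2, 1e-300)) + 1.0)
    return NullModelFit(
        kind="ancova",
        beta0=beta,
        D0=np.zeros((2, 2)),
        sigma_eps2=s2,
        X=X,
        residuals=resid,
        loglik=loglik,
        converged=True,
        boundary=False,
        n_subjects=n,
        n_obs=n,
        subject=np.arange(n),
        time=np.full(n, float(t1)),
    )
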