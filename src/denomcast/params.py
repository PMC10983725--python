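"""Parameter containers for the three surveillance regression relationships.

The disease-incidence model (relationship 1) is a zero-inflated NB2 regression
with a log-linear dispersion submodel and a per-centre latent Gaussian AR(1)
process on the log-mean scale.  The two patient/occupancy ratio models
(relationships 2 and 3) are Gaussian regressions whose residual variance is
itself modelled log-linearly.

Covariate scaling convention (fixed throughout the package): percentages of
adult and male persons enter the linear predictors per 10 percentage points,
and counts of patients / residents enter per 10 persons.  All containers store
coefficients on that scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ZinbAr1Params",
    "GaussianDispParams",
    "FitResult",
]


@dataclass
class ZinbAr1Params:
    """Full parameter vector of the zero-inflated NB2-AR(1) incidence model.

    Attributes
    ----------
    beta : conditional (log-link) coefficients
        ``[intercept, adult_per10, male_per10, n_pat_per10, *extras]``.
    beta_zi : zero-inflation (logit-link) coefficients ``[intercept, n_pat_per10]``.
    beta_disp : dispersion (log-link on theta) coefficients ``[intercept, REG]``.
    sigma_ar : marginal standard deviation of the latent AR(1) process (>= 0).
    phi : lag-1 correlation of the latent process, in (-1, 1).
    """

    beta: np.ndarray
    beta_zi: np.ndarray
    beta_disp: np.ndarray
    sigma_ar: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_zi = np.asarray(self.beta_zi, dtype=float)
        self.beta_disp = np.asarray(self.beta_disp, dtype=float)
        if self.sigma_ar < 0:
            raise ValueError("sigma_ar must be non-negative")
        if not (-1.0 < self.phi < 1.0):
            raise ValueError("phi must lie strictly inside (-1, 1)")

    @property
    def n_params(self) -> int:
        k = self.beta.size + self.beta_zi.size + self.beta_disp.size
        if self.sigma_ar > 0:
            k += 2  # sigma_ar and phi are free
        return k

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "beta_zi": self.beta_zi.tolist(),
            "beta_disp": self.beta_disp.tolist(),
            "sigma_ar": self.sigma_ar,
            "phi": self.phi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZinbAr1Params":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            beta_zi=np.asarray(d["beta_zi"], dtype=float),
            beta_disp=np.asarray(d["beta_disp"], dtype=float),
            sigma_ar=float(d.get("sigma_ar", 0.0)),
            phi=float(d.get("phi", 0.0)),
        )


@dataclass
class GaussianDispParams:
    """Mean and log-variance coefficients of a Gaussian ratio model.

    ``mean_coefs`` multiply the mean-model design matrix; ``logvar_coefs``
    multiply the variance-model design matrix (log link, so the residual
    variance is ``exp(z @ logvar_coefs) > 0``).
    """

    mean_coefs: np.ndarray
    logvar_coefs: np.ndarray

    def __post_init__(self) -> None:
        self.mean_coefs = np.asarray(self.mean_coefs, dtype=float)
        self.logvar_coefs = np.asarray(self.logvar_coefs, dtype=float)

    @property
    def n_params(self) -> int:
        return self.mean_coefs.size + self.logvar_coefs.size

    @property
    def constant_variance(self) -> float | None:
        """Residual variance when the variance model is intercept-only."""
        if self.logvar_coefs.size == 1:
            return float(math.exp(self.logvar_coefs[0]))
        return None

    def to_dict(self) -> dict:
        return {
            "mean_coefs": self.mean_coefs.tolist(),
            "logvar_coefs": self.logvar_coefs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianDispParams":
        return cls(
            mean_coefs=np.asarray(d["mean_coefs"], dtype=float),
            logvar_coefs=np.asarray(d["logvar_coefs"], dtype=float),
        )


@dataclass
class FitResult:
    """Maximum-likelihood fit summary for any of the three relationships.

    ``theta`` is the packed free-parameter vector on the optimisation scale,
    ``params`` the structured parameter object, ``vcov`` the Wald covariance
    of ``theta`` (may be ``None`` when standard errors were not requested).
    """

    model: str
    params: object
    param_names: list[str]
    theta: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    vcov: np.ndarray | None = None
    boundary_sigma: bool = False
    trace: dict = field(default_factory=dict)
    dataset_tag: str = ""

    @property
    def k(self) -> int:
        return int(np.asarray(self.theta).size)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, np.inf))

    def to_dict(self) -> dict:
        from .fit import wald_ci  # local import to avoid a cycle

        d = {
            "schema_version": 1,
            "model": self.model,
            "param_names": list(self.param_names),
            "theta": np.asarray(self.theta).tolist(),
            "params": self.params.to_dict(),
            "params_class": type(self.params).__name__,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "k": self.k,
            "converged": self.converged,
            "boundary_sigma": self.boundary_sigma,
            "dataset_tag": self.dataset_tag,
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
        }
        if self.vcov is not None:
            lo, hi = wald_ci(self)
            d["ci_lower"] = lo.tolist()
            d["ci_upper"] = hi.tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        pcls = {"ZinbAr1Params": ZinbAr1Params, "GaussianDispParams": GaussianDispParams}[
            d["params_class"]
        ]
        return cls(
            model=d["model"],
            params=pcls.from_dict(d["params"]),
            param_names=list(d["param_names"]),
            theta=np.asarray(d["theta"], dtype=float),
            loglik=float(d["loglik"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            vcov=None if d.get("vcov") is None else np.asarray(d["vcov"], dtype=float),
            boundary_sigma=bool(d.get("boundary_sigma", False)),
            dataset_tag=d.get("dataset_tag", ""),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
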