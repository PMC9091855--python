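"""Stage one of the two-stage analysis: the repeatability mixed model.

Adult weight records are modelled with fixed effects of sex and age and
independent random intercepts for individual identity (repeated measures),
birth year and capture year:

    w = X b + Z_id u_id + Z_by u_by + Z_cy u_cy + e .

Variance components are estimated by REML and the best linear unbiased
predictions of the individual-identity effects become the adjusted
phenotypes handed to genomic prediction.  Uncertainty in these adjusted
phenotypes is deliberately not propagated downstream; the posterior
machinery downstream accounts for uncertainty in the breeding values
themselves.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

from .phenotypes import validate_phenotypes

logger = logging.getLogger(__name__)

COMPONENTS = ("id", "birth_year", "capture_year")


class ConvergenceError(RuntimeError):
    """REML optimiser failed; carries the optimiser result as ``trace``."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class VarianceComponents:
    sigma2_id: float
    sigma2_by: float
    sigma2_cy: float
    sigma2_e: float
    se: dict
    fixed_effects: pd.Series

    def as_dict(self) -> dict:
        return {
            "sigma2_id": self.sigma2_id, "sigma2_by": self.sigma2_by,
            "sigma2_cy": self.sigma2_cy, "sigma2_e": self.sigma2_e,
        }


def _one_hot(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


class RepeatabilityModel:
    """REML repeatability model on raw repeated weight records.

    Parameters
    ----------
    records : phenotype table (id, weight, capture_age, capture_year,
        capture_month, sex).
    age_as : "categorical" (whole years of age, default) or "polynomial"
        (linear + quadratic in months).
    max_age_class : ages at or above this many years share one class.
    """

    def __init__(self, records: pd.DataFrame, age_as: str = "categorical",
                 max_age_class: int = 9):
        records = validate_phenotypes(records)
        if records["id"].nunique() < 2:
            raise ValueError("at least two individuals required")
        self.records = records.reset_index(drop=True)
        self.age_as = age_as
        n = len(records)
        y = self.records["weight"].to_numpy(float)

        cols = {"intercept": np.ones(n)}
        if self.records["sex"].nunique() > 1:
            cols["sex_M"] = (self.records["sex"] == "M").astype(float).to_numpy()
        if age_as == "categorical":
            age_cls = np.minimum(
                (self.records["capture_age"] // 12).astype(int), max_age_class
            )
            levels = sorted(age_cls.unique())
            for lv in levels[1:]:
                cols[f"age_{lv}"] = (age_cls == lv).astype(float).to_numpy()
        elif age_as == "polynomial":
            a = self.records["capture_age"].to_numpy(float)
            a = (a - a.mean()) / max(a.std(), 1e-12)
            cols["age"] = a
            cols["age2"] = a * a
        else:
            raise ValueError("age_as must be 'categorical' or 'polynomial'")
        self.X = np.column_stack(list(cols.values()))
        self.fixed_names = list(cols)

        ids, id_codes = np.unique(self.records["id"], return_inverse=True)
        by = (self.records["capture_year"].to_numpy(int)
              - (self.records["capture_age"].to_numpy(int) // 12))
        by_levels, by_codes = np.unique(by, return_inverse=True)
        cy_levels, cy_codes = np.unique(self.records["capture_year"], return_inverse=True)

        self.levels = {"id": ids, "birth_year": by_levels, "capture_year": cy_levels}
        self.Z = sparse.hstack([
            _one_hot(id_codes, len(ids)),
            _one_hot(by_codes, len(by_levels)),
            _one_hot(cy_codes, len(cy_levels)),
        ]).tocsr()
        self.block_sizes = [len(ids), len(by_levels), len(cy_levels)]
        self.y = y
        self._id_codes = id_codes

        # sufficient statistics for the REML objective
        self._XtX = self.X.T @ self.X
        self._XtZ = (self.Z.T @ self.X).T
        self._ZtZ = (self.Z.T @ self.Z).toarray()
        self._Xty = self.X.T @ y
        self._Zty = self.Z.T @ y
        self._yty = float(y @ y)

    # -- REML machinery -------------------------------------------------
    def _neg2_reml(self, variances: np.ndarray, want_blup: bool = False):
        """-2 restricted log-likelihood via the mixed-model-equation identity.

        -2 l_R = n_* log sigma2_e + log|G| + log|C| + y'Py  (+ const),
        with C the MME coefficient matrix on the R^-1 scale.
        """
        s2_id, s2_by, s2_cy, s2_e = variances
        n, p = self.X.shape
        q = sum(self.block_sizes)
        ginv = np.concatenate([
            np.full(self.block_sizes[0], 1.0 / s2_id),
            np.full(self.block_sizes[1], 1.0 / s2_by),
            np.full(self.block_sizes[2], 1.0 / s2_cy),
        ])
        C = np.zeros((p + q, p + q))
        C[:p, :p] = self._XtX / s2_e
        C[:p, p:] = self._XtZ / s2_e
        C[p:, :p] = self._XtZ.T / s2_e
        C[p:, p:] = self._ZtZ / s2_e
        C[p + np.arange(q), p + np.arange(q)] += ginv
        rhs = np.concatenate([self._Xty, self._Zty]) / s2_e
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf if not want_blup else (np.inf, None)
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        logdet_C = 2.0 * np.log(np.diag(cf[0])).sum()
        logdet_G = (self.block_sizes[0] * np.log(s2_id)
                    + self.block_sizes[1] * np.log(s2_by)
                    + self.block_sizes[2] * np.log(s2_cy))
        yPy = self._yty / s2_e - rhs @ sol
        val = n * np.log(s2_e) + logdet_G + logdet_C + yPy
        if want_blup:
            return val, sol
        return val

    def fit(self, start: np.ndarray | None = None,
            compute_se: bool = True) -> "RepeatabilityResults":
        y = self.y
        vy = float(np.var(y, ddof=1)) if len(y) > 1 else 0.0
        if vy <= 1e-12:
            # degenerate data: every record identical
            vc = VarianceComponents(0.0, 0.0, 0.0, 0.0, se={},
                                    fixed_effects=pd.Series({"intercept": float(y.mean())}))
            adj = pd.DataFrame({
                "id": self.levels["id"],
                "value": np.zeros(len(self.levels["id"])),
                "n_records": pd.Series(self._id_codes).value_counts().sort_index().to_numpy(),
            })
            return RepeatabilityResults(self, vc, adj, converged=True, neg2_loglik=np.nan)

        floor = vy * 1e-8
        if start is None:
            start = np.array([0.3 * vy, 0.1 * vy, 0.1 * vy, 0.5 * vy])
        obj = lambda t: self._neg2_reml(np.exp(t))
        res = optimize.minimize(
            obj, np.log(np.maximum(start, floor)), method="L-BFGS-B",
            bounds=[(np.log(floor), np.log(vy * 1e4))] * 4,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if not res.success and not np.isfinite(res.fun):
            raise ConvergenceError(f"REML failed: {res.message}", trace=res)
        variances = np.exp(res.x)
        at_floor = variances <= floor * 1.01
        names = ("sigma2_id", "sigma2_by", "sigma2_cy", "sigma2_e")
        for k in np.nonzero(at_floor)[0]:
            warnings.warn(f"variance component {names[k]} pinned at the zero boundary")
        variances = np.where(at_floor, 0.0, variances)

        val, sol = self._neg2_reml(np.maximum(variances, floor), want_blup=True)
        p = self.X.shape[1]
        fixed = pd.Series(sol[:p], index=self.fixed_names)
        u_id = sol[p:p + self.block_sizes[0]]
        if at_floor[0]:
            u_id = np.zeros_like(u_id)
        se = self._standard_errors(np.maximum(variances, floor)) if compute_se else {}
        vc = VarianceComponents(
            sigma2_id=float(variances[0]), sigma2_by=float(variances[1]),
            sigma2_cy=float(variances[2]), sigma2_e=float(variances[3]),
            se=se, fixed_effects=fixed,
        )
        counts = np.bincount(self._id_codes, minlength=self.block_sizes[0])
        adjusted = pd.DataFrame({
            "id": self.levels["id"], "value": u_id, "n_records": counts,
        })
        return RepeatabilityResults(self, vc, adjusted, converged=bool(res.success),
                                    neg2_loglik=float(val))

    def _standard_errors(self, variances: np.ndarray) -> dict:
        """Asymptotic SEs from a central-difference Hessian of -2 l_R."""
        names = ("sigma2_id", "sigma2_by", "sigma2_cy", "sigma2_e")
        k = len(variances)
        h = np.maximum(1e-4 * variances, 1e-10)
        H = np.zeros((k, k))

        def f(v):
            return self._neg2_reml(np.maximum(v, 1e-12))

        for i in range(k):
            for j in range(i, k):
                vpp = variances.copy(); vpp[i] += h[i]; vpp[j] += h[j]
                vpm = variances.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
                vmp = variances.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
                vmm = variances.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (4 * h[i] * h[j])
        try:
            cov = 2.0 * linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except linalg.LinAlgError:
            se = np.full(k, np.nan)
        return dict(zip(names, se))


@dataclass
class RepeatabilityResults:
    """Variance components, fixed effects and adjusted phenotypes."""

    model: RepeatabilityModel
    varcomp: VarianceComponents
    adjusted: pd.DataFrame     # id, value, n_records
    converged: bool
    neg2_loglik: float

    @property
    def repeatability(self) -> float:
        v = self.varcomp
        tot = v.sigma2_id + v.sigma2_by + v.sigma2_cy + v.sigma2_e
        return v.sigma2_id / tot if tot > 0 else 0.0

    def summary(self) -> str:
        v = self.varcomp
        lines = [
            "Repeatability mixed model (REML)",
            "=" * 46,
            f"records: {len(self.model.y)}   individuals: {self.model.block_sizes[0]}",
            "",
            "variance components        estimate        SE",
        ]
        for name, val in v.as_dict().items():
            se = v.se.get(name, np.nan)
            lines.append(f"  {name:<22} {val:10.4f} {se:9.4f}")
        lines.append(f"  repeatability          {self.repeatability:10.4f}")
        lines.append("")
        lines.append("fixed effects")
        for name, val in v.fixed_effects.items():
            lines.append(f"  {name:<22} {val:10.4f}")
        return "\n".join(lines)

    def write_adjusted(self, path) -> None:
        self.adjusted.to_csv(path, sep="\t", index=False)


def fit_repeatability_model(records: pd.DataFrame, age_as: str = "categorical"):
    """Convenience wrapper returning (VarianceComponents, adjusted phenotypes)."""
    res = RepeatabilityModel(records, age_as=age_as).fit()
    return res.varcomp, res.adjusted
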