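"""Maximum-likelihood fitting of the nested epistasis-model family.

The observation model is Gaussian on the natural-log scale with a residual SD
shared across genotypes, so the profiled log-likelihood is a monotone function
of the residual sum of squares:

    loglik = -(n / 2) * (ln(2 * pi * RSS / n) + 1)

and maximizing the likelihood is minimizing the RSS.  Because the mean is
constant within each (background, focal) cell, the RSS decomposes into a
fixed within-cell part plus a weighted lack-of-fit over cell means — fits
touch only the per-cell sufficient statistics, so cost is independent of the
number of fruits.

ADDITIVE, CONSTANT and IDIOSYNCRATIC are linear in their parameters and are
solved in closed form (weighted least squares on cell means, exactly the
Gaussian MLE).  PROPORTIONAL and SIGMOID involve the background means
nonlinearly, so all parameters (betas included) are optimized jointly by
multi-start bounded L-BFGS-B, with starts jittered around a two-stage
estimate (plug-in sample means for the betas, then the focal parameters fit
to the observed per-background effects).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import optimize
from scipy.special import expit

from .design import ExperimentDesign
from .exceptions import DesignError
from .families import FOCAL_PARAM_NAMES, ModelFamily, ModelParams, effect_function, n_mean_params
from .phenotypes import PhenotypeTable

F = ModelFamily

SIGMA_FLOOR = 1e-8  # guards log(0) for degenerate zero-noise fits

_DEFAULT_BOUNDS = {"A": (-5.0, 5.0), "r": (1e-3, 10.0), "delta0": (-5.0, 5.0), "eps": (-50.0, 50.0)}


def profiled_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood with sigma^2 profiled at RSS / n."""
    s2 = max(rss / n, SIGMA_FLOOR**2)
    return -(n / 2.0) * (math.log(2.0 * math.pi * s2) + 1.0)


@dataclass
class _Cells:
    """Per-(background, m) sufficient statistics of the log phenotypes."""

    b: np.ndarray  # background index per cell
    m: np.ndarray  # focal indicator per cell
    n: np.ndarray  # fruits per cell
    ybar: np.ndarray  # cell mean of log phenotype
    sw: float  # total within-cell sum of squares
    n_total: int
    genotype_ids: list[str]  # one observed genotype id per cell

    def rss(self, mu: np.ndarray) -> float:
        d = self.ybar - mu
        return self.sw + float(self.n @ (d * d))


def _build_cells(table: PhenotypeTable, design: ExperimentDesign) -> _Cells:
    y = table.log_values()
    gids = table.genotype_ids().to_numpy()
    order: dict[str, int] = {}
    b_list: list[int] = []
    m_list: list[int] = []
    cells_y: list[list[float]] = []
    cell_gids: list[str] = []
    for i, gid in enumerate(gids):
        if gid not in order:
            b, m = design.cell_of(gid)
            order[gid] = len(b_list)
            b_list.append(b)
            m_list.append(m)
            cells_y.append([])
            cell_gids.append(gid)
        cells_y[order[gid]].append(y[i])
    n = np.array([len(v) for v in cells_y], dtype=float)
    ybar = np.array([float(np.mean(v)) for v in cells_y])
    sw = float(sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in cells_y))
    return _Cells(
        b=np.array(b_list),
        m=np.array(m_list),
        n=n,
        ybar=ybar,
        sw=sw,
        n_total=int(n.sum()),
        genotype_ids=cell_gids,
    )


class EpistasisModel:
    """One family of the nested epistasis model, bound to a phenotype table.

    Parameters
    ----------
    table : PhenotypeTable
        Per-fruit phenotypes.
    design : ExperimentDesign, optional
        Background/focal decomposition; inferred from the table when omitted
        (``focal_locus`` then required).
    family : ModelFamily or str
        One of additive, constant, proportional, sigmoid, idiosyncratic.

    Examples
    --------
    >>> model = EpistasisModel(table, family="sigmoid", focal_locus="cle9")
    >>> res = model.fit(seed=1)
    >>> res.effect("fas"), res.llf
    """

    def __init__(
        self,
        table: PhenotypeTable,
        family: ModelFamily | str,
        design: ExperimentDesign | None = None,
        focal_locus: str | None = None,
    ):
        self.family = ModelFamily.coerce(family)
        self.table = table
        if design is None:
            if focal_locus is None:
                raise DesignError("provide a design or a focal_locus to infer one")
            design = ExperimentDesign.from_table(table, focal_locus)
        self.design = design
        self.cells = _build_cells(table, design)
        # every background must be observed without the focal mutation so
        # that beta_b is anchored by data
        seen0 = {int(b) for b, m in zip(self.cells.b, self.cells.m) if m == 0}
        missing0 = [l for i, l in enumerate(design.backgrounds) if i not in seen0]
        if missing0:
            raise DesignError(f"backgrounds observed only with the focal mutation: {missing0}")
        missing1 = sorted({(l, 1) for l, m in design.missing_cells if m == 1})
        if missing1:
            warnings.warn(
                f"focal-mutant cell unobserved for background(s) {[l for l, _ in missing1]}; "
                "fit proceeds on observed cells",
                stacklevel=2,
            )
        # data fingerprint so results from different tables refuse to be LRT'd
        y = table.log_values()
        self._fingerprint = (len(y), round(float(y.sum()), 9), round(float((y * y).sum()), 9))

    @classmethod
    def from_dataframe(cls, df, family, focal_locus, design=None) -> "EpistasisModel":
        return cls(PhenotypeTable(df), family=family, design=design, focal_locus=focal_locus)

    # ------------------------------------------------------------------ #
    # likelihood surface                                                  #
    # ------------------------------------------------------------------ #
    def _effects_vec(self, beta: np.ndarray, focal: dict[str, float]) -> np.ndarray:
        """E(b) for every background, vectorized over the background grid."""
        f = self.family
        if f is F.ADDITIVE:
            return np.full(len(beta), focal["delta"])
        if f is F.CONSTANT:
            e = np.full(len(beta), focal["delta_mut"])
            e[0] = focal["delta_wt"]
            return e
        if f is F.PROPORTIONAL:
            return focal["delta0"] * (1.0 + focal["eps"] * (beta - beta[0]))
        if f is F.SIGMOID:
            return focal["A"] * expit((beta - focal["x0"]) / focal["r"])
        if f is F.IDIOSYNCRATIC:
            return np.array([focal.get(l, np.nan) for l in self.design.backgrounds])
        raise AssertionError(f)

    def _mu_cells(self, beta: np.ndarray, focal: dict[str, float]) -> np.ndarray:
        eff = self._effects_vec(beta, focal)
        # np.where (not m * eff) so an undefined effect in an unobserved
        # focal cell (NaN) cannot poison the m = 0 cells
        return beta[self.cells.b] + np.where(self.cells.m == 1, eff[self.cells.b], 0.0)

    def rss(self, params: ModelParams) -> float:
        beta = np.array([params.beta[l] for l in self.design.backgrounds])
        return self.cells.rss(self._mu_cells(beta, params.focal))

    def loglik(self, params: ModelParams, sigma: float | None = None) -> float:
        """Gaussian log-likelihood at ``params``.

        With ``sigma`` given, the full Gaussian log-likelihood at that sigma;
        otherwise sigma is profiled (its MLE RSS/n plugged in).  A zero RSS is
        floored at ``SIGMA_FLOOR`` with a warning.
        """
        rss = self.rss(params)
        n = self.cells.n_total
        if rss <= n * SIGMA_FLOOR**2:
            warnings.warn("zero residual variance: log-likelihood floored (degenerate fit)", stacklevel=2)
        if sigma is None:
            return profiled_loglik(rss, n)
        s2 = max(sigma, SIGMA_FLOOR) ** 2
        return -0.5 * (n * math.log(2.0 * math.pi * s2) + rss / s2)

    # ------------------------------------------------------------------ #
    # fitting                                                             #
    # ------------------------------------------------------------------ #
    def fit(
        self,
        n_starts: int = 32,
        seed: int = 0,
        tol: float = 1e-9,
        max_iter: int = 500,
        method: str = "auto",
    ) -> "EpistasisResults":
        """Maximum-likelihood fit.

        ``method="auto"`` uses the closed-form WLS solution for the linear
        families and joint multi-start L-BFGS-B for proportional/sigmoid;
        ``"numeric"`` forces the optimizer for every family (used for
        cross-checks); ``"two-stage"`` freezes the betas at the per-background
        sample means and optimizes only the focal parameters.
        """
        family = self.family
        linear = family in (F.ADDITIVE, F.CONSTANT, F.IDIOSYNCRATIC)
        if method == "auto" and linear:
            vec, names, converged, used = self._fit_linear(), None, True, 1
            vec, names = vec
        elif method in ("numeric", "auto", "two-stage"):
            vec, names, converged, used = self._fit_numeric(
                n_starts=n_starts, seed=seed, tol=tol, max_iter=max_iter,
                freeze_beta=(method == "two-stage"),
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return self._results(vec, names, converged, used, seed)

    # -- linear families: exact WLS on cell means ------------------------- #
    def _design_matrix(self) -> tuple[np.ndarray, list[str]]:
        cells, nb = self.cells, self.design.n_backgrounds
        labels = self.design.backgrounds
        cols: list[np.ndarray] = []
        names: list[str] = []
        for i, l in enumerate(labels):
            cols.append((cells.b == i).astype(float))
            names.append(f"beta[{l}]")
        f = self.family
        if f is F.ADDITIVE:
            cols.append(cells.m.astype(float))
            names.append("delta")
        elif f is F.CONSTANT:
            cols.append(((cells.b == 0) & (cells.m == 1)).astype(float))
            names.append("delta_wt")
            cols.append(((cells.b != 0) & (cells.m == 1)).astype(float))
            names.append("delta_mut")
        elif f is F.IDIOSYNCRATIC:
            for i, l in enumerate(labels):
                cols.append(((cells.b == i) & (cells.m == 1)).astype(float))
                names.append(f"delta[{l}]")
        else:
            raise AssertionError(f)
        return np.column_stack(cols), names

    def _fit_linear(self) -> tuple[np.ndarray, list[str]]:
        X, names = self._design_matrix()
        w = np.sqrt(self.cells.n)
        theta, *_ = np.linalg.lstsq(X * w[:, None], self.cells.ybar * w, rcond=None)
        return theta, names

    # -- nonlinear families: joint multi-start optimization --------------- #
    def _two_stage_start(self) -> tuple[np.ndarray, dict[str, float]]:
        cells = self.cells
        nb = self.design.n_backgrounds
        beta = np.zeros(nb)
        d = np.full(nb, np.nan)
        for i in range(nb):
            sel0 = (cells.b == i) & (cells.m == 0)
            beta[i] = float(np.average(cells.ybar[sel0], weights=cells.n[sel0]))
            sel1 = (cells.b == i) & (cells.m == 1)
            if sel1.any():
                d[i] = float(np.average(cells.ybar[sel1], weights=cells.n[sel1])) - beta[i]
        obs = ~np.isnan(d)
        if self.family is F.PROPORTIONAL:
            x = beta[obs] - beta[0]
            if obs.sum() >= 2 and np.ptp(x) > 0:
                slope, intercept = np.polyfit(x, d[obs], 1)
            else:
                slope, intercept = 0.0, float(np.nanmean(d))
            delta0 = intercept if abs(intercept) > 1e-12 else 1e-12
            focal = {"delta0": float(delta0), "eps": float(slope / delta0)}
        else:  # SIGMOID
            strongest = int(np.argmax(np.where(obs, beta, -np.inf)))
            a0 = d[strongest] if obs.any() else 0.1
            focal = {
                "A": float(a0),
                "x0": float(np.median(beta)),
                "r": max(float(np.ptp(beta)) / 8.0, 0.05),
            }
        return beta, focal

    def _fit_numeric(
        self, n_starts: int, seed: int, tol: float, max_iter: int, freeze_beta: bool
    ) -> tuple[np.ndarray, list[str], bool, int]:
        labels = self.design.backgrounds
        nb = len(labels)
        beta0, focal0 = (
            self._two_stage_start()
            if self.family in (F.PROPORTIONAL, F.SIGMOID)
            else (self._fit_linear_beta_focal())
        )
        fnames = list(
            FOCAL_PARAM_NAMES.get(self.family, tuple(f"delta[{l}]" for l in labels))
        )
        names = [f"beta[{l}]" for l in labels] + fnames
        cells = self.cells

        span = float(np.ptp(beta0)) if nb > 1 else 1.0
        lo_b, hi_b = beta0.min() - 1.0, beta0.max() + 1.0
        bounds: list[tuple[float, float]] = [(b - 1.5, b + 1.5) for b in beta0]
        for nm in fnames:
            if nm == "x0":
                bounds.append((lo_b, hi_b))
            else:
                bounds.append(_DEFAULT_BOUNDS.get(nm.split("[")[0], (-10.0, 10.0)))

        is_idio = self.family is F.IDIOSYNCRATIC

        def unpack(theta: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
            if freeze_beta:
                beta, fv = beta0, theta
            else:
                beta, fv = theta[:nb], theta[nb:]
            focal = dict(zip(fnames, fv))
            if is_idio:
                focal = {l: focal[f"delta[{l}]"] for l in labels}
            return beta, focal

        def objective(theta: np.ndarray) -> float:
            beta, focal = unpack(theta)
            return cells.rss(self._mu_cells(beta, focal))

        x00 = np.array([focal0.get(nm, 0.0) for nm in fnames])
        full0 = x00 if freeze_beta else np.concatenate([beta0, x00])
        use_bounds = bounds[nb:] if freeze_beta else bounds

        rng = np.random.default_rng(seed)
        starts = [full0]
        if self.family is F.SIGMOID and not freeze_beta:
            # deterministic boundary starts covering the nested limits the
            # jittered starts rarely reach: a constant effect (x0 below every
            # background, r -> 0 so everything is saturated) and no effect
            d_mean = focal0["A"] if math.isfinite(focal0["A"]) else 0.0
            for corner in (
                {"A": d_mean, "x0": beta0.min() - 0.999, "r": 1.5e-3},
                {"A": 0.0, "x0": float(np.median(beta0)), "r": 0.5},
            ):
                starts.append(np.concatenate([beta0, [corner[nm] for nm in fnames]]))
        for _ in range(max(0, n_starts - 1)):
            s = full0.copy()
            k = 0 if freeze_beta else nb
            if not freeze_beta:
                s[:nb] = beta0 + rng.normal(0.0, 0.05, nb)
            for j, nm in enumerate(fnames):
                if nm == "x0":
                    s[k + j] = rng.uniform(beta0.min(), beta0.max())
                elif nm == "r":
                    s[k + j] = float(np.exp(rng.uniform(np.log(0.02), np.log(max(span, 0.2)))))
                else:
                    s[k + j] = full0[k + j] + rng.normal(0.0, 0.3)
            starts.append(np.clip(s, [b[0] for b in use_bounds], [b[1] for b in use_bounds]))

        solutions: list[tuple[float, float, np.ndarray, bool]] = []
        for s in starts:
            res = optimize.minimize(
                objective, s, method="L-BFGS-B", bounds=use_bounds,
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
            )
            k = 0 if freeze_beta else nb
            focal_norm = float(np.linalg.norm(res.x[k:]))
            solutions.append((float(res.fun), focal_norm, res.x, bool(res.success)))

        n = cells.n_total
        best_rss = min(s[0] for s in solutions)
        # near-ties in loglik resolved toward the smaller focal-parameter norm
        ll_best = profiled_loglik(best_rss, n)
        tied = [s for s in solutions if profiled_loglik(s[0], n) >= ll_best - max(tol, 1e-9)]
        _, _, x_best, ok = min(tied, key=lambda s: (s[1], s[0]))
        converged = ok or any(s[3] for s in tied)
        beta, _ = unpack(x_best)
        fv = x_best if freeze_beta else x_best[nb:]
        vec = np.concatenate([beta, fv])
        return vec, names, converged, len(starts)

    def _fit_linear_beta_focal(self):
        # numeric-path starting point for linear families (cross-check mode)
        theta, names = self._fit_linear()
        nb = self.design.n_backgrounds
        focal_names = names[nb:]
        return theta[:nb], dict(zip(focal_names, theta[nb:]))

    # ------------------------------------------------------------------ #
    def _results(self, vec, names, converged, n_starts_used, seed) -> "EpistasisResults":
        labels = self.design.backgrounds
        nb = len(labels)
        if names is None:
            raise AssertionError
        beta = {l: float(vec[i]) for i, l in enumerate(labels)}
        if self.family is F.IDIOSYNCRATIC:
            focal = {l: float(vec[nb + i]) for i, l in enumerate(labels)}
            # unobserved focal cells leave delta_b unidentified (lstsq -> 0)
            observed1 = {
                labels[int(b)] for b, m in zip(self.cells.b, self.cells.m) if m == 1
            }
            focal = {l: v for l, v in focal.items() if l in observed1}
        else:
            fnames = names[nb:]
            focal = {nm: float(v) for nm, v in zip(fnames, vec[nb:])}
        params = ModelParams(
            family=self.family, beta=beta, focal=focal, reference=labels[0]
        )
        rss = self.rss(params)
        n = self.cells.n_total
        params.sigma = math.sqrt(max(rss / n, SIGMA_FLOOR**2))
        return EpistasisResults(
            model=self,
            params=params,
            param_names=list(names),
            param_vector=np.asarray(vec, dtype=float),
            rss=rss,
            converged=converged,
            n_starts_used=n_starts_used,
            seed=seed,
        )


@dataclass
class EpistasisResults:
    """A fitted epistasis model: estimates, uncertainties and diagnostics."""

    model: EpistasisModel
    params: ModelParams
    param_names: list[str]
    param_vector: np.ndarray
    rss: float
    converged: bool
    n_starts_used: int
    seed: int
    _bse: np.ndarray | None = field(default=None, repr=False)

    # -- core quantities ---------------------------------------------------
    @property
    def family(self) -> ModelFamily:
        return self.params.family

    @property
    def nobs(self) -> int:
        return self.model.cells.n_total

    @property
    def df_model(self) -> int:
        """Number of mean-structure parameters."""
        return n_mean_params(self.family, self.model.design)

    @property
    def llf(self) -> float:
        return profiled_loglik(self.rss, self.nobs)

    @property
    def degenerate(self) -> bool:
        return self.rss <= self.nobs * SIGMA_FLOOR**2

    @property
    def aic(self) -> float:
        return 2.0 * (self.df_model + 1) - 2.0 * self.llf  # +1 for sigma

    @property
    def sigma(self) -> float:
        return float(self.params.sigma)

    @property
    def fitted_means(self) -> dict[str, float]:
        """Fitted mean log phenotype for every observed genotype."""
        cells = self.model.cells
        beta = np.array([self.params.beta[l] for l in self.model.design.backgrounds])
        mu = self.model._mu_cells(beta, self.params.focal)
        return {gid: float(v) for gid, v in zip(cells.genotype_ids, mu)}

    def effect(self, background: str) -> float:
        """Focal-mutation effect E(b) on mean log locule number."""
        return effect_function(self.family, self.params, background)

    def effects(self) -> dict[str, float]:
        out = {}
        for l in self.model.design.backgrounds:
            try:
                out[l] = self.effect(l)
            except KeyError:
                pass
        return out

    # -- uncertainties -------------------------------------------------------
    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors (Gauss–Newton, shared-sigma Gaussian)."""
        if self._bse is None:
            self._bse = self._compute_bse()
        return self._bse

    def _compute_bse(self) -> np.ndarray:
        cells = self.model.cells
        nb = self.model.design.n_backgrounds
        theta = self.param_vector
        labels = self.model.design.backgrounds
        fnames = self.param_names[nb:]

        def mu_of(vec: np.ndarray) -> np.ndarray:
            beta = vec[:nb]
            focal = dict(zip(fnames, vec[nb:]))
            if self.family is F.IDIOSYNCRATIC:
                focal = {l: focal[f"delta[{l}]"] for l in labels if f"delta[{l}]" in focal}
            return self.model._mu_cells(beta, focal)

        p = len(theta)
        J = np.empty((len(cells.b), p))
        h = 1e-6
        for j in range(p):
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            J[:, j] = (mu_of(up) - mu_of(dn)) / (2 * h)
        W = cells.n
        dof = max(self.nobs - self.df_model, 1)
        s2 = self.rss / dof
        cov = s2 * np.linalg.pinv((J * W[:, None]).T @ J)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Epistasis model fit (Gaussian ML on log locule counts)",
            "=" * 58,
            f"family: {self.family.value:<14} nobs: {self.nobs}",
            f"loglik: {self.llf:.4f}   AIC: {self.aic:.4f}   sigma: {self.sigma:.4f}",
            f"mean params: {self.df_model}   converged: {self.converged}"
            f"   starts: {self.n_starts_used}   seed: {self.seed}",
            "-" * 58,
            f"{'parameter':<22}{'estimate':>12}{'std err':>12}",
        ]
        for nm, v, se in zip(self.param_names, self.param_vector, self.bse):
            lines.append(f"{nm:<22}{v:>12.4f}{se:>12.4f}")
        lines.append("-" * 58)
        lines.append(f"{'background':<22}{'effect E(b)':>12}")
        for l, e in self.effects().items():
            lines.append(f"{l:<22}{e:>12.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "params": self.params.to_dict(),
            "param_names": self.param_names,
            "param_vector": [float(v) for v in self.param_vector],
            "bse": [float(v) for v in self.bse],
            "loglik": self.llf,
            "rss": self.rss,
            "nobs": self.nobs,
            "n_mean_params": self.df_model,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "seed": self.seed,
            "fitted_means": self.fitted_means,
            "effects": self.effects(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def fit_model(
    table: PhenotypeTable,
    design: ExperimentDesign,
    family: ModelFamily | str,
    n_starts: int = 32,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 500,
    method: str = "auto",
) -> EpistasisResults:
    """Functional wrapper: fit one family to a table under a design."""
    return EpistasisModel(table, family=family, design=design).fit(
        n_starts=n_starts, seed=seed, tol=tol, max_iter=max_iter, method=method
    )


def model_loglik(
    table: PhenotypeTable,
    design: ExperimentDesign,
    family: ModelFamily | str,
    params: ModelParams,
    sigma: float | None = None,
) -> float:
    """Gaussian log-likelihood of ``params`` on a table (sigma profiled if None)."""
    return EpistasisModel(table, family=family, design=design).loglik(params, sigma=sigma)
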