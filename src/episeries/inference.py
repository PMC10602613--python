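"""Model comparison and effect estimation for the epistasis-model family.

Covers the standard analysis chain: likelihood-ratio tests between nested
fits (chi-square reference, with a parametric bootstrap for the approximately
nested sigmoid comparisons), a full nested-model scan, background-specific
focal effects with standard errors, the epistatic-variance decomposition, and
saturated-effect prediction from a fitted sigmoid.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .design import ExperimentDesign
from .exceptions import (
    DegenerateVarianceError,
    NotConvergedError,
    NotNestedError,
    OptimizationFailureError,
)
from .families import ModelFamily, nesting_of
from .model import EpistasisResults, fit_model
from .phenotypes import COUNT_COLUMN, LOG_COLUMN, PhenotypeTable, summarize

F = ModelFamily

#: the comparison sequence of the nested-model scan
SCAN_PAIRS: tuple[tuple[F, F], ...] = (
    (F.ADDITIVE, F.CONSTANT),
    (F.ADDITIVE, F.PROPORTIONAL),
    (F.ADDITIVE, F.IDIOSYNCRATIC),
    (F.CONSTANT, F.IDIOSYNCRATIC),
    (F.PROPORTIONAL, F.IDIOSYNCRATIC),
    (F.ADDITIVE, F.SIGMOID),
    (F.CONSTANT, F.SIGMOID),
    (F.PROPORTIONAL, F.SIGMOID),
    (F.SIGMOID, F.IDIOSYNCRATIC),
)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a small family against a bigger one."""

    family_small: ModelFamily
    family_big: ModelFamily
    stat: float
    df: int
    p: float
    nesting: str  # "strict" or "approximate"
    bootstrap_p: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tail = f", bootstrap p={self.bootstrap_p:.4g}" if self.bootstrap_p is not None else ""
        return (
            f"LRT {self.family_small.value} vs {self.family_big.value}: "
            f"stat={self.stat:.4g}, df={self.df}, p={self.p:.4g} ({self.nesting}{tail})"
        )


def likelihood_ratio_test(
    fit_small: EpistasisResults, fit_big: EpistasisResults, tol: float = 1e-6
) -> LRTResult:
    """LRT with the chi-square reference; df = difference in mean parameters.

    The pair must be (strictly or approximately) nested and both fits must be
    on the same data.  A log-likelihood deficit of the bigger model beyond
    ``tol`` signals an optimization failure and is raised, not silently
    clipped.
    """
    nesting = nesting_of(fit_small.family, fit_big.family)
    if fit_small.model._fingerprint != fit_big.model._fingerprint:
        raise ValueError("LRT requires both fits on identical data")
    if fit_small.degenerate and fit_big.degenerate:
        # both families interpolate the data exactly: no evidence either way
        stat = 0.0
    else:
        stat = 2.0 * (fit_big.llf - fit_small.llf)
    if stat < -tol and nesting == "strict":
        raise OptimizationFailureError(
            f"loglik({fit_big.family.value}) < loglik({fit_small.family.value}) "
            f"by {-stat / 2:.3g}: refit with more starts"
        )
    # approximately nested pairs (e.g. constant vs sigmoid) can genuinely fit
    # worse than the "smaller" family; that is zero evidence for the big one
    stat = max(stat, 0.0)
    df = fit_big.df_model - fit_small.df_model
    if df > 0:
        p = float(stats.chi2.sf(stat, df))
    else:
        p = 1.0  # degenerate designs where the families coincide
    return LRTResult(fit_small.family, fit_big.family, stat, df, p, nesting)


def bootstrap_lrt(
    table: PhenotypeTable,
    design: ExperimentDesign,
    family_small: ModelFamily | str,
    family_big: ModelFamily | str,
    B: int = 199,
    seed: int = 0,
    n_starts: int = 8,
) -> LRTResult:
    """Parametric-bootstrap LRT (simulating under the small model's fit).

    p = (1 + #{stat_b >= stat_obs}) / (B + 1).  Replicates whose refits do not
    converge are dropped and counted (warning above 5%).  Deterministic for a
    fixed seed.
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    family_small = ModelFamily.coerce(family_small)
    family_big = ModelFamily.coerce(family_big)
    fs = fit_model(table, design, family_small, n_starts=n_starts, seed=seed)
    fb = fit_model(table, design, family_big, n_starts=n_starts, seed=seed)
    obs = likelihood_ratio_test(fs, fb)
    if obs.stat == 0.0:
        return LRTResult(family_small, family_big, 0.0, obs.df, obs.p, obs.nesting, 1.0)

    rng = np.random.default_rng(seed)
    mu = fs.fitted_means
    sigma = fs.sigma
    df0 = table.df
    gids = table.genotype_ids().to_numpy()
    mu_rows = np.array([mu[g] for g in gids])

    exceed = 0
    dropped = 0
    used = 0
    for b in range(B):
        sim = df0.copy()
        y = mu_rows + rng.normal(0.0, sigma, len(mu_rows))
        if COUNT_COLUMN in sim.columns:
            sim = sim.drop(columns=[COUNT_COLUMN])
        sim[LOG_COLUMN] = y
        t = PhenotypeTable(sim)
        rs = fit_model(t, design, family_small, n_starts=n_starts, seed=seed + 1 + b)
        rb = fit_model(t, design, family_big, n_starts=n_starts, seed=seed + 1 + b)
        if not (rs.converged and rb.converged):
            dropped += 1
            continue
        stat_b = max(2.0 * (rb.llf - rs.llf), 0.0)
        used += 1
        if stat_b >= obs.stat:
            exceed += 1
    if dropped > 0.05 * B:
        warnings.warn(f"bootstrap: {dropped}/{B} replicates dropped (non-convergence)", stacklevel=2)
    p_boot = (1.0 + exceed) / (used + 1.0)
    return LRTResult(family_small, family_big, obs.stat, obs.df, obs.p, obs.nesting, p_boot)


@dataclass
class ScanResults:
    """All five family fits plus the standard LRT comparison sequence."""

    fits: dict[ModelFamily, EpistasisResults]
    lrts: list[LRTResult]

    def fit(self, family: ModelFamily | str) -> EpistasisResults:
        return self.fits[ModelFamily.coerce(family)]

    def lrt(self, small: ModelFamily | str, big: ModelFamily | str) -> LRTResult:
        small, big = ModelFamily.coerce(small), ModelFamily.coerce(big)
        for r in self.lrts:
            if r.family_small is small and r.family_big is big:
                return r
        raise KeyError(f"no LRT {small.value} vs {big.value} in the scan")

    def aic_table(self) -> pd.DataFrame:
        rows = [
            {
                "family": fam.value,
                "loglik": res.llf,
                "n_mean_params": res.df_model,
                "aic": res.aic,
                "converged": res.converged,
            }
            for fam, res in self.fits.items()
        ]
        return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)

    def summary(self) -> str:
        lines = ["Nested epistasis model scan", "=" * 66, "Fits:"]
        for _, row in self.aic_table().iterrows():
            lines.append(
                f"  {row['family']:<14} loglik={row['loglik']:>12.3f}  "
                f"k={row['n_mean_params']:>3}  AIC={row['aic']:>12.3f}"
            )
        lines.append("Likelihood-ratio tests:")
        for r in self.lrts:
            star = "" if r.nesting == "strict" else " (approx. nesting)"
            boot = f"  boot p={r.bootstrap_p:.4g}" if r.bootstrap_p is not None else ""
            lines.append(
                f"  {r.family_small.value:<13} vs {r.family_big.value:<13} "
                f"stat={r.stat:>10.3f} df={r.df:>2} p={_fmt_p(r.p)}{boot}{star}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fits": {fam.value: res.to_dict() for fam, res in self.fits.items()},
            "lrts": [
                {
                    "small": r.family_small.value,
                    "big": r.family_big.value,
                    "stat": r.stat,
                    "df": r.df,
                    "p": r.p,
                    "nesting": r.nesting,
                    "bootstrap_p": r.bootstrap_p,
                }
                for r in self.lrts
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _fmt_p(p: float) -> str:
    return f"{p:.4f}" if p >= 1e-4 else f"{p:.2e}"


def nested_model_scan(
    table: PhenotypeTable,
    design: ExperimentDesign,
    n_starts: int = 32,
    seed: int = 0,
    bootstrap_B: int = 0,
) -> ScanResults:
    """Fit all five families and run the standard LRT sequence.

    With ``bootstrap_B`` > 0 the approximately nested sigmoid comparisons also
    get a parametric-bootstrap p-value.
    """
    fits = {
        fam: fit_model(table, design, fam, n_starts=n_starts, seed=seed)
        for fam in ModelFamily
    }
    lrts: list[LRTResult] = []
    for small, big in SCAN_PAIRS:
        r = likelihood_ratio_test(fits[small], fits[big])
        if bootstrap_B > 0 and r.nesting == "approximate":
            r = bootstrap_lrt(
                table, design, small, big, B=bootstrap_B, seed=seed, n_starts=max(4, n_starts // 4)
            )
        lrts.append(r)
    return ScanResults(fits=fits, lrts=lrts)


# --------------------------------------------------------------------------- #
# background-specific effects                                                  #
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class EffectEstimate:
    """Observed focal effect in one background, from genotype summaries.

    ``delta_log`` is the difference in mean log locule number between the
    focal mutant and its background genotype; ``se`` combines the two
    genotype-level standard errors in quadrature.  ``percent_change`` is the
    percent change in the arithmetic mean count (NaN for continuous tables,
    or computed from ``delta_log`` with ``log_scale_percent``).
    """

    background: str
    delta_log: float
    se: float
    percent_change: float
    n_background: int
    n_mutant: int
    genotype_background: str
    genotype_mutant: str


def pairwise_effects(
    table: PhenotypeTable,
    design: ExperimentDesign,
    log_scale_percent: bool = False,
) -> list[EffectEstimate]:
    """Focal-mutation effect estimate for every background with both cells.

    Backgrounds whose focal-mutant genotype is unobserved are omitted with a
    warning.
    """
    summaries = {s.genotype_id: s for s in summarize(table)}
    by_cell: dict[tuple[int, int], str] = {}
    for gid, cell in design.cell_map.items():
        if gid in summaries:
            by_cell[cell] = gid
    out: list[EffectEstimate] = []
    for i, b in enumerate(design.backgrounds):
        g0 = by_cell.get((i, 0))
        g1 = by_cell.get((i, 1))
        if g0 is None or g1 is None:
            warnings.warn(f"background {b!r}: missing cell, effect omitted", stacklevel=2)
            continue
        s0, s1 = summaries[g0], summaries[g1]
        delta = s1.mean_log - s0.mean_log
        se0 = 0.0 if math.isnan(s0.se_log) else s0.se_log
        se1 = 0.0 if math.isnan(s1.se_log) else s1.se_log
        se = math.sqrt(se0**2 + se1**2)
        if log_scale_percent:
            pct = 100.0 * (math.exp(delta) - 1.0)
        elif table.has_counts:
            pct = 100.0 * (s1.mean_count / s0.mean_count - 1.0)
        else:
            pct = float("nan")
        out.append(
            EffectEstimate(
                background=b,
                delta_log=float(delta),
                se=float(se),
                percent_change=float(pct),
                n_background=s0.n_fruits,
                n_mutant=s1.n_fruits,
                genotype_background=g0,
                genotype_mutant=g1,
            )
        )
    return out


def effects_to_frame(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in effects])


# --------------------------------------------------------------------------- #
# epistatic-variance decomposition                                              #
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class VarianceDecomposition:
    """Share of the epistatic variance captured by an intermediate model.

    The epistatic variance is what the saturated (idiosyncratic) model
    explains beyond the additive model; the fraction is

        (RSS_additive - RSS_model) / (RSS_additive - RSS_idiosyncratic)
    """

    family: ModelFamily
    rss_additive: float
    rss_model: float
    rss_idiosyncratic: float
    level: str = "fruit"

    @property
    def fraction(self) -> float:
        return (self.rss_additive - self.rss_model) / (
            self.rss_additive - self.rss_idiosyncratic
        )

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def epistatic_variance_fraction(
    table: PhenotypeTable,
    design: ExperimentDesign,
    family: ModelFamily | str,
    n_starts: int = 32,
    seed: int = 0,
    level: str = "fruit",
) -> VarianceDecomposition:
    """Epistatic-variance fraction of ``family`` between additive and saturated.

    ``level="fruit"`` uses fruit-level residual sums of squares (the
    n-weighted genotype-mean version is algebraically identical);
    ``level="genotype"`` recomputes the lack-of-fit on unweighted genotype
    means.
    """
    family = ModelFamily.coerce(family)
    fits = {
        fam: fit_model(table, design, fam, n_starts=n_starts, seed=seed)
        for fam in {F.ADDITIVE, F.IDIOSYNCRATIC, family}
    }
    for fam, res in fits.items():
        if not res.converged:
            raise NotConvergedError(f"{fam.value} fit did not converge")

    if level == "fruit":
        ra, rm, ri = (fits[f].rss for f in (F.ADDITIVE, family, F.IDIOSYNCRATIC))
    elif level == "genotype":
        cells = fits[F.ADDITIVE].model.cells
        ra, rm, ri = (
            float(np.sum((cells.ybar - _cell_mu(fits[f])) ** 2))
            for f in (F.ADDITIVE, family, F.IDIOSYNCRATIC)
        )
    else:
        raise ValueError(f"level must be 'fruit' or 'genotype', got {level!r}")
    if ra - ri <= max(1e-12, 1e-9 * ra):
        raise DegenerateVarianceError(
            "no epistatic variance: additive and idiosyncratic RSS coincide"
        )
    return VarianceDecomposition(
        family=family, rss_additive=ra, rss_model=rm, rss_idiosyncratic=ri, level=level
    )


def _cell_mu(res: EpistasisResults) -> np.ndarray:
    fm = res.fitted_means
    return np.array([fm[g] for g in res.model.cells.genotype_ids])


# --------------------------------------------------------------------------- #
# sigmoid predictions                                                           #
# --------------------------------------------------------------------------- #
def predict_saturated_effect(sigmoid_fit: EpistasisResults) -> float:
    """Upper asymptote A of a fitted sigmoid: the saturated focal effect."""
    _require_sigmoid(sigmoid_fit)
    return float(sigmoid_fit.params.focal["A"])


def predict_effect_at(sigmoid_fit: EpistasisResults, background_strength: float) -> float:
    """Sigmoid-predicted focal effect at a background strength x (mean log scale)."""
    _require_sigmoid(sigmoid_fit)
    f = sigmoid_fit.params.focal
    z = (background_strength - f["x0"]) / f["r"]
    return float(f["A"] * expit(z))


def _require_sigmoid(res: EpistasisResults) -> None:
    if res.family is not F.SIGMOID:
        raise NotNestedError(f"expected a sigmoid fit, got {res.family.value}")
    if not res.converged:
        raise NotConvergedError("sigmoid fit did not converge")
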