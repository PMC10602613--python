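"""Synthetic phenotype generator mirroring the fitted observation model.

Generates per-fruit tables with the hierarchical replication structure of the
field experiments: for each genotype, N plants carrying a shared log-scale
plant effect ~ Normal(0, tau^2), each with n fruits whose log phenotype is
mu(genotype) + plant effect + Normal(0, sigma^2).  Optionally the continuous
log phenotypes are discretized to integer locule counts with
count = max(min_count, round(exp(y))) (round half to even), emulating real
fruit counts which are bounded below by two locules.

The generator's truth is expressed through the same mean-structure contract
the models fit (a :class:`~episeries.families.ModelParams`), so recovery and
calibration studies compare like with like.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .families import ModelFamily, ModelParams, effect_function
from .genotypes import Genotype, LocusState
from .model import EpistasisModel
from .phenotypes import COUNT_COLUMN, LOG_COLUMN, PhenotypeTable

F = ModelFamily

#: default allelic-series grid: WT fruits have ~2 locules, the strongest
#: promoter alleles are near-null with >15, so the true background means span
#: ln 2 ~ 0.69 to ln 15 ~ 2.7 on the log scale.
DEFAULT_BACKGROUNDS: tuple[tuple[str, float], ...] = (
    ("WT", math.log(2.0)),
    ("Pro-2", 0.90),
    ("Pro-5", 1.10),
    ("Pro-11", 1.35),
    ("Pro-18", 1.60),
    ("Pro-24", 1.85),
    ("Pro-30", 2.05),
    ("Pro-35", 2.20),
    ("fas", 2.30),
    ("Pro-40", 2.45),
    ("Pro-22", 2.55),
    ("Pro-28", 2.70),
)


@dataclass
class SimDesign:
    """Generative specification for one two-locus factorial experiment.

    Parameters
    ----------
    backgrounds : (label, true beta_b) pairs, reference "WT" included.
    focal_locus : "wus" or "cle9".
    true_family : which epistasis mode generates the focal effects.
    focal_params : the family's focal parameters (idiosyncratic: label -> delta_b).
    n_plants, n_fruits : replication per genotype (N plants, n fruits/plant).
    plant_sd : tau, the log-scale plant random-effect SD (default 0: the
        generator then matches the default likelihood exactly).
    residual_sd : sigma, the fruit-level log-scale noise SD.
    discretize : emit integer locule counts instead of continuous log values.
    min_count : floor for discretized counts (tomato fruits have >= 2 locules).
    trial_ids : one simulated trial per id (replicated field trials).
    """

    backgrounds: Sequence[tuple[str, float]] = DEFAULT_BACKGROUNDS
    focal_locus: str = "wus"
    true_family: ModelFamily | str = F.ADDITIVE
    focal_params: Mapping[str, float] = field(default_factory=lambda: {"delta": 0.3})
    n_plants: int = 5
    n_fruits: int = 10
    plant_sd: float = 0.0
    residual_sd: float = 0.2
    discretize: bool = False
    min_count: int = 2
    seed: int = 0
    trial_ids: Sequence[str] = ("T1",)

    def __post_init__(self) -> None:
        self.true_family = ModelFamily.coerce(self.true_family)
        if self.residual_sd < 0 or self.plant_sd < 0:
            raise ValueError("residual_sd and plant_sd must be >= 0")
        if self.n_plants < 1 or self.n_fruits < 1:
            raise ValueError("n_plants and n_fruits must be >= 1")
        labels = [l for l, _ in self.backgrounds]
        if "WT" not in labels:
            raise ValueError("backgrounds must include the reference 'WT'")

    def true_params(self) -> ModelParams:
        return ModelParams(
            family=self.true_family,
            beta={l: float(b) for l, b in self.backgrounds},
            focal=dict(self.focal_params),
            reference="WT",
            sigma=self.residual_sd,
        )


@dataclass
class SimTruth:
    """Ground truth echoed alongside a simulated table."""

    params: ModelParams
    mu: dict[str, float]  # genotype_id -> true mean log phenotype
    effects: dict[str, float]  # background -> true E(b)
    seed: int
    rng: str = "numpy.random.default_rng(PCG64)"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "mu": self.mu,
            "effects": self.effects,
            "seed": self.seed,
            "rng": self.rng,
        }

    def write(self, path: str | Path) -> None:
        _atomic_write(path, json.dumps(self.to_dict(), indent=2))


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _genotype_id(clv3: str, focal_locus: str, m: int, wus_state: str = "WT") -> str:
    wus = wus_state
    cle9 = "WT"
    if focal_locus == "wus":
        wus = "lc" if m else "WT"
    else:
        cle9 = "null" if m else "WT"
    return Genotype(LocusState(clv3, wus, cle9)).genotype_id


def _emit_rows(
    rows: list,
    rng: np.random.Generator,
    trial: str,
    gid: str,
    mu: float,
    design: SimDesign,
) -> None:
    clv3, wus, cle9 = gid.split("|")
    for j in range(design.n_plants):
        p = rng.normal(0.0, design.plant_sd) if design.plant_sd > 0 else 0.0
        eps = (
            rng.normal(0.0, design.residual_sd, design.n_fruits)
            if design.residual_sd > 0
            else np.zeros(design.n_fruits)
        )
        for k in range(design.n_fruits):
            y = mu + p + eps[k]
            row = {
                "trial_id": trial,
                "clv3_allele": clv3,
                "wus": wus,
                "cle9": cle9,
                "plant_id": f"P{j + 1}",
                "fruit_id": f"F{k + 1}",
            }
            if design.discretize:
                row[COUNT_COLUMN] = int(max(design.min_count, np.rint(math.exp(y))))
            else:
                row[LOG_COLUMN] = y
            rows.append(row)


def simulate_experiment(design: SimDesign) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate a complete 2 x (K+1) factorial experiment.

    Fully determined by ``design.seed``; returns the table plus a
    :class:`SimTruth` whose means obey the model mean-structure contract.
    """
    params = design.true_params()
    rng = np.random.default_rng(design.seed)
    mu_map: dict[str, float] = {}
    eff: dict[str, float] = {}
    rows: list[dict] = []
    for label, beta in design.backgrounds:
        e = effect_function(design.true_family, params, label)
        eff[label] = float(e)
        for m in (0, 1):
            gid = _genotype_id(label, design.focal_locus, m)
            mu = beta + (e if m else 0.0)
            mu_map[gid] = float(mu)
            for trial in design.trial_ids:
                _emit_rows(rows, rng, trial, gid, mu, design)
    table = PhenotypeTable(pd.DataFrame(rows))
    return table, SimTruth(params=params, mu=mu_map, effects=eff, seed=design.seed)


def simulate_triple_factorial(
    backgrounds: Sequence[tuple[str, float]],
    cell_effects: Mapping[tuple[str, int, int], float],
    design: SimDesign | None = None,
    **design_kwargs,
) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate a combinatorially complete (CLV3 allele) x wus x cle9 factorial.

    ``cell_effects`` maps (clv3 label, wus in {0,1}, cle9 in {0,1}) to the
    offset of that cell's mean from the background beta; the (b, 0, 0) cells
    default to 0.  Every one of the K x 2 x 2 cells is emitted, so sign
    reversals in particular triple cells are directly expressible.  The truth
    is framed for the compound-background analysis (focal locus cle9,
    backgrounds = CLV3 allele x wus state).
    """
    if design is None:
        design = SimDesign(backgrounds=backgrounds, focal_locus="cle9", **design_kwargs)
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    mu_map: dict[str, float] = {}
    beta_cb: dict[str, float] = {}
    eff_cb: dict[str, float] = {}
    for label, beta in backgrounds:
        for w in (0, 1):
            cb = _compound_label(label, w)
            mu0 = beta + float(cell_effects.get((label, w, 0), 0.0))
            mu1 = beta + float(cell_effects.get((label, w, 1), 0.0))
            beta_cb[cb] = mu0
            eff_cb[cb] = mu1 - mu0
            for c in (0, 1):
                gid = Genotype(
                    LocusState(label, "lc" if w else "WT", "null" if c else "WT")
                ).genotype_id
                mu = mu1 if c else mu0
                mu_map[gid] = float(mu)
                for trial in design.trial_ids:
                    _emit_rows(rows, rng, trial, gid, mu, design)
    params = ModelParams(
        family=F.IDIOSYNCRATIC, beta=beta_cb, focal=dict(eff_cb), reference="WT",
        sigma=design.residual_sd,
    )
    table = PhenotypeTable(pd.DataFrame(rows))
    return table, SimTruth(params=params, mu=mu_map, effects=eff_cb, seed=design.seed)


def _compound_label(clv3: str, wus01: int) -> str:
    parts = []
    if clv3 != "WT":
        parts.append(clv3)
    if wus01:
        parts.append("wus-lc")
    return " ".join(parts) if parts else "WT"


# --------------------------------------------------------------------------- #
# recovery studies                                                             #
# --------------------------------------------------------------------------- #
@dataclass
class RecoveryReport:
    """Bias, RMSE and +/-2 SE coverage of the true family's focal parameters."""

    family: ModelFamily
    n_reps: int
    n_converged: int
    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float]
    estimates: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "n_reps": self.n_reps,
            "n_converged": self.n_converged,
            "bias": self.bias,
            "rmse": self.rmse,
            "coverage": self.coverage,
        }


def recovery_study(
    design: SimDesign,
    n_reps: int,
    seed: int = 0,
    n_starts: int = 16,
) -> RecoveryReport:
    """Refit the generating family to ``n_reps`` fresh replicates.

    Reports per-focal-parameter bias and RMSE, plus the fraction of converged
    replicates whose estimate falls within +/-2 standard errors of the truth.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    family = ModelFamily.coerce(design.true_family)
    truth = dict(design.focal_params)
    rows = []
    n_conv = 0
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps)]
    for r, s in enumerate(child_seeds):
        d = SimDesign(**{**design.__dict__, "seed": s})
        table, _ = simulate_experiment(d)
        res = EpistasisModel(table, family=family, focal_locus=design.focal_locus).fit(
            n_starts=n_starts, seed=s
        )
        if res.converged:
            n_conv += 1
        nb = res.model.design.n_backgrounds
        se = dict(zip(res.param_names[nb:], res.bse[nb:]))
        row = {"rep": r, "converged": res.converged}
        for name, tv in truth.items():
            est = res.params.focal.get(name, float("nan"))
            key = name if name in se else f"delta[{name}]"
            row[f"{name}_hat"] = est
            row[f"{name}_se"] = se.get(key, float("nan"))
        rows.append(row)
    est_df = pd.DataFrame(rows)
    bias, rmse, cover = {}, {}, {}
    conv = est_df[est_df["converged"]]
    for name, tv in truth.items():
        e = conv[f"{name}_hat"].to_numpy(dtype=float)
        s = conv[f"{name}_se"].to_numpy(dtype=float)
        bias[name] = float(np.mean(e - tv))
        rmse[name] = float(np.sqrt(np.mean((e - tv) ** 2)))
        with np.errstate(invalid="ignore"):
            cover[name] = float(np.mean(np.abs(e - tv) <= 2.0 * s))
    return RecoveryReport(
        family=family,
        n_reps=n_reps,
        n_converged=n_conv,
        bias=bias,
        rmse=rmse,
        coverage=cover,
        estimates=est_df,
    )


# --------------------------------------------------------------------------- #
# synthetic study-scale stand-in                                                #
# --------------------------------------------------------------------------- #
#: alleles used in the triple-mutant factorial (subset spanning the series)
TRIPLE_ALLELES: tuple[str, ...] = ("WT", "Pro-2", "Pro-11", "Pro-18", "Pro-22", "Pro-28")
#: extra single mutants phenotyped outside the two factorials
EXTRA_SINGLES: tuple[tuple[str, float], ...] = (
    ("Pro-3", 0.95),
    ("Pro-7", 1.20),
    ("Pro-15", 1.70),
    ("Pro-19", 2.00),
)


def _orthogonal_idiosyncrasy(betas: np.ndarray, rms: float = 0.25) -> np.ndarray:
    """Per-background effect perturbations orthogonal to the constant and
    proportional contrasts.

    The returned vector (one entry per mutant background) sums to zero and is
    orthogonal to the background-strength covariate, so at the generator's
    truth neither the constant nor the proportional family improves on the
    additive fit — only the saturated model does.  Deterministic: built from
    an alternating sign pattern by Gram-Schmidt, scaled to the requested RMS.
    """
    k = len(betas)
    raw = np.array([(-1.0) ** i * (1.0 + 0.3 * i) for i in range(k)])
    x = betas - betas.mean()
    for v in (np.ones(k), x):
        raw = raw - (raw @ v) / (v @ v) * v
    return raw * (rms / np.sqrt(np.mean(raw**2)))


def simulate_study_standin(seed: int = 0, n_plants: int = 8, n_fruits: int = 40):
    """Synthetic stand-in for a full allelic-series study (three experiments).

    This is a synthetic dataset emulating the *scale and structure* of a
    complete study — it is not real phenotype data.  It combines:

    * a WUS experiment: 2 trials of the 2 x 12 factorial (focal wus-lc) whose
      focal effects are additive (0.25) plus idiosyncratic perturbations
      (RMS 0.06) constructed orthogonal to the constant and proportional
      contrasts;
    * a CLE9 experiment: 3 trials of the 2 x 12 factorial (focal cle9-null)
      whose focal effects follow the sigmoid (A=0.4, x0=1.5, r=0.2) plus
      small idiosyncratic residuals (SD 0.02);
    * a triple-mutant factorial: 6 x 2 x 2 with a sign reversal of the cle9
      effect in the Pro-11 wus-lc background;
    * four extra single mutants phenotyped on their own.

    Together: 46 distinct genotypes and > 30,000 fruit records.  Continuous
    log phenotypes are emitted (the analysis scale), so generator
    discretization bias cannot masquerade as epistasis.

    Returns a dict with the ``combined`` table, the per-experiment tables
    (``wus``, ``cle9``, ``triple``) and their :class:`SimTruth` objects.
    """
    root = np.random.SeedSequence(seed)
    s_wus, s_cle9, s_triple, s_extra = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )
    backgrounds = list(DEFAULT_BACKGROUNDS)
    labels = [l for l, _ in backgrounds]
    betas = np.array([b for _, b in backgrounds])

    # WUS experiment: additive + orthogonal idiosyncrasy.  RMS 0.06 keeps the
    # constant/proportional comparisons truly null (the jointly-fitted
    # proportional model can absorb strong idiosyncrasy through its curvature)
    # while the saturated model still detects the pattern overwhelmingly.
    e = np.zeros(len(labels))
    e[1:] = _orthogonal_idiosyncrasy(betas[1:], rms=0.06)
    wus_focal = {l: 0.25 + float(e[i]) for i, l in enumerate(labels)}
    wus_design = SimDesign(
        backgrounds=backgrounds, focal_locus="wus", true_family=F.IDIOSYNCRATIC,
        focal_params=wus_focal, n_plants=n_plants, n_fruits=n_fruits,
        residual_sd=0.2, seed=s_wus, trial_ids=("W1", "W2"),
    )
    wus_table, wus_truth = simulate_experiment(wus_design)

    # CLE9 experiment: sigmoid + small idiosyncratic residuals
    sig = ModelParams(
        family=F.SIGMOID, beta=dict(zip(labels, betas)),
        focal={"A": 0.4, "x0": 1.5, "r": 0.2},
    )
    pert_rng = np.random.default_rng(s_cle9)
    cle9_focal = {
        l: float(effect_function(F.SIGMOID, sig, l) + pert_rng.normal(0.0, 0.02))
        for l in labels
    }
    cle9_design = SimDesign(
        backgrounds=backgrounds, focal_locus="cle9", true_family=F.IDIOSYNCRATIC,
        focal_params=cle9_focal, n_plants=n_plants, n_fruits=max(n_fruits * 3 // 4, 1),
        residual_sd=0.2, seed=s_cle9, trial_ids=("C1", "C2", "C3"),
    )
    cle9_table, cle9_truth = simulate_experiment(cle9_design)

    # triple factorial with the Pro-11 reversal
    tri_bg = [(l, b) for l, b in backgrounds if l in TRIPLE_ALLELES]
    cell_effects: dict[tuple[str, int, int], float] = {}
    for l, b in tri_bg:
        w = wus_focal[l]
        c_single = cle9_focal[l]
        c_in_lc = 0.35  # cle9 effect approaches its saturated level in triples
        cell_effects[(l, 1, 0)] = w
        cell_effects[(l, 0, 1)] = c_single
        cell_effects[(l, 1, 1)] = w + (-0.30 if l == "Pro-11" else c_in_lc)
    tri_table, tri_truth = simulate_triple_factorial(
        tri_bg, cell_effects,
        design=SimDesign(
            backgrounds=tri_bg, focal_locus="cle9", n_plants=n_plants,
            n_fruits=max(n_fruits * 3 // 4, 1), residual_sd=0.2, seed=s_triple,
            trial_ids=("X1",),
        ),
    )

    # extra single mutants (their own background, no focal mutant cell)
    extra_rng = np.random.default_rng(s_extra)
    rows: list[dict] = []
    extra_design = SimDesign(
        backgrounds=(("WT", math.log(2.0)),) + EXTRA_SINGLES, focal_locus="wus",
        true_family=F.ADDITIVE, focal_params={"delta": 0.0}, n_plants=n_plants,
        n_fruits=n_fruits, residual_sd=0.2, seed=s_extra, trial_ids=("E1",),
    )
    for label, beta in EXTRA_SINGLES:
        gid = _genotype_id(label, "wus", 0)
        _emit_rows(rows, extra_rng, "E1", gid, beta, extra_design)
    extra_table = PhenotypeTable(pd.DataFrame(rows))

    combined = PhenotypeTable(
        pd.concat(
            [wus_table.df, cle9_table.df, tri_table.df, extra_table.df],
            ignore_index=True,
        )
    )
    return {
        "combined": combined,
        "wus": wus_table,
        "wus_truth": wus_truth,
        "cle9": cle9_table,
        "cle9_truth": cle9_truth,
        "triple": tri_table,
        "triple_truth": tri_truth,
    }


def write_simulation(
    table: PhenotypeTable, truth: SimTruth, tsv_path: str | Path, truth_path: str | Path
) -> None:
    """Atomically write the phenotype TSV and the truth JSON (seed embedded)."""
    buf = table.df.to_csv(sep="\t", index=False)
    _atomic_write(tsv_path, buf)
    truth.write(truth_path)
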