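import pandas as pd
import pytest

import episeries as ep


def make_table(rows):
    """Build a PhenotypeTable from (trial, clv3, wus, cle9, plant, fruit, count) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["trial_id", "clv3_allele", "wus", "cle9", "plant_id", "fruit_id", "locule_count"],
    )
    return ep.PhenotypeTable(df)


def pair_table(counts_background, counts_mutant, background="fas", focal="wus"):
    """Two-genotype table: one background genotype and its focal mutant,
    plus a WT reference cell so the design has its reference background."""
    rows = []
    for i, c in enumerate(counts_background):
        rows.append(("T1", background, "WT", "WT", "P1", f"F{i}", c))
    mut = ("lc", "WT") if focal == "wus" else ("WT", "null")
    for i, c in enumerate(counts_mutant):
        rows.append(("T1", background, mut[0], mut[1], "P1", f"F{i}", c))
    for i, c in enumerate(counts_background):
        rows.append(("T1", "WT", "WT", "WT", "P1", f"F{i}", c))
        rows.append(("T1", "WT", mut[0], mut[1], "P1", f"F{i}", c))
    return make_table(rows)


SMALL_BACKGROUNDS = [("WT", 0.7), ("Pro-5", 1.3), ("fas", 2.3)]
MID_BACKGROUNDS = [("WT", 0.7), ("b1", 1.1), ("b2", 1.5), ("b3", 1.9), ("b4", 2.3), ("b5", 2.7)]


@pytest.fixture(scope="session")
def additive_sim():
    sd = ep.SimDesign(
        backgrounds=MID_BACKGROUNDS,
        true_family="additive",
        focal_params={"delta": 0.3},
        n_plants=3,
        n_fruits=20,
        residual_sd=0.2,
        seed=11,
    )
    return ep.simulate_experiment(sd)


@pytest.fixture(scope="session")
def additive_table(additive_sim):
    return additive_sim[0]


@pytest.fixture(scope="session")
def additive_design(additive_table):
    return ep.ExperimentDesign.from_table(additive_table, "wus")


@pytest.fixture(scope="session")
def sigmoid_sim():
    sd = ep.SimDesign(
        backgrounds=[("WT", 0.7)] + [(f"b{i}", 0.7 + 0.3 * i) for i in range(1, 8)],
        focal_locus="cle9",
        true_family="sigmoid",
        focal_params={"A": 0.4, "x0": 1.5, "r": 0.2},
        n_plants=5,
        n_fruits=30,
        residual_sd=0.2,
        seed=17,
    )
    return ep.simulate_experiment(sd)


@pytest.fixture(scope="session")
def sigmoid_table(sigmoid_sim):
    return sigmoid_sim[0]


@pytest.fixture(scope="session")
def sigmoid_design(sigmoid_table):
    return ep.ExperimentDesign.from_table(sigmoid_table, "cle9")
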