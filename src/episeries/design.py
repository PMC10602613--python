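"""Factorial experiment designs: backgrounds x focal-mutation presence.

Every genotype in a two-way epistasis experiment decomposes into a
*background* b (the joint state of the non-focal loci) and a focal-mutation
indicator m (0 = focal locus wild type, 1 = mutant).  For the allelic-series
experiments the background is simply the CLV3 promoter allele; for the
triple-mutant factorial the background is a compound (CLV3 allele, WUS state)
label and the focal locus is CLE9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DesignError
from .genotypes import Genotype, LocusState
from .phenotypes import PhenotypeTable

_LOCI = ("clv3_allele", "wus", "cle9")
REFERENCE = "WT"


def background_label(states: dict[str, str], focal_locus: str) -> str:
    """Human-readable background label from the non-focal locus states.

    The all-wild-type background is ``"WT"``.  A non-WT state at the second
    non-focal locus yields a compound label, e.g. ``"Pro-11 wus-lc"``.
    """
    parts = []
    clv3 = states["clv3_allele"]
    other = [l for l in _LOCI[1:] if l != focal_locus]
    if clv3 != REFERENCE:
        parts.append(clv3)
    for locus in other:
        if states[locus] != REFERENCE:
            parts.append(f"{locus}-{states[locus]}")
    return " ".join(parts) if parts else REFERENCE


@dataclass
class ExperimentDesign:
    """Mapping from observed genotypes to (background, focal) cells.

    Attributes
    ----------
    focal_locus : ``"wus"`` or ``"cle9"``
    backgrounds : background labels, reference (``"WT"``) first, then in
        increasing order of background mean log phenotype.
    cell_map : genotype_id -> (background index, m)
    missing_cells : (background, m) cells with no observed genotype.
    """

    focal_locus: str
    backgrounds: list[str]
    cell_map: dict[str, tuple[int, int]]
    background_states: dict[str, dict[str, str]] = field(default_factory=dict)
    missing_cells: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.focal_locus not in ("wus", "cle9"):
            raise DesignError(f"focal_locus must be 'wus' or 'cle9', got {self.focal_locus!r}")
        if not self.backgrounds or self.backgrounds[0] != REFERENCE:
            raise DesignError("reference background 'WT' must be present and listed first")

    @property
    def n_backgrounds(self) -> int:
        return len(self.backgrounds)

    @property
    def reference(self) -> str:
        return self.backgrounds[0]

    def cell_of(self, genotype_id: str) -> tuple[int, int]:
        try:
            return self.cell_map[genotype_id]
        except KeyError:
            raise DesignError(f"genotype {genotype_id!r} not covered by the design") from None

    def genotype_of_cell(self, background: str, m: int) -> str:
        """Canonical genotype id of a (background, m) cell."""
        states = dict(self.background_states[background])
        states[self.focal_locus] = _mutant_state(self.focal_locus) if m else REFERENCE
        return Genotype(LocusState(**states)).genotype_id

    @classmethod
    def from_table(cls, table: PhenotypeTable, focal_locus: str) -> "ExperimentDesign":
        """Infer the design from the genotypes observed in a table.

        Backgrounds are ordered reference-first, then by the mean log
        phenotype of the un-mutated (m = 0) cell — the allelic-series order
        used throughout for background strength.
        """
        if focal_locus not in ("wus", "cle9"):
            raise DesignError(f"focal_locus must be 'wus' or 'cle9', got {focal_locus!r}")
        df = table.df
        y = table.log_values()
        gids = table.genotype_ids()

        info: dict[str, tuple[str, int, dict[str, str]]] = {}
        mean0: dict[str, float] = {}
        for gid, idx in gids.groupby(gids).groups.items():
            g = Genotype.from_id(str(gid))
            states = {
                "clv3_allele": g.loci.clv3_allele,
                "wus": g.loci.wus,
                "cle9": g.loci.cle9,
            }
            m = int(states[focal_locus] != REFERENCE)
            bg_states = {k: v for k, v in states.items() if k != focal_locus}
            label = background_label({**bg_states, focal_locus: REFERENCE}, focal_locus)
            info[str(gid)] = (label, m, bg_states)
            if m == 0:
                mean0[label] = float(np.mean(y[np.asarray(idx)]))

        labels = {label for label, _, _ in info.values()}
        if REFERENCE not in labels:
            raise DesignError("no all-wild-type reference background observed")
        others = sorted(
            (l for l in labels if l != REFERENCE),
            key=lambda l: (mean0.get(l, np.inf), l),
        )
        backgrounds = [REFERENCE] + others
        b_index = {l: i for i, l in enumerate(backgrounds)}

        cell_map: dict[str, tuple[int, int]] = {}
        bg_states_by_label: dict[str, dict[str, str]] = {}
        seen: set[tuple[str, int]] = set()
        for gid, (label, m, bg_states) in info.items():
            cell_map[gid] = (b_index[label], m)
            full = dict(bg_states)
            full[focal_locus] = REFERENCE
            bg_states_by_label[label] = full
            seen.add((label, m))
        missing = [(l, m) for l in backgrounds for m in (0, 1) if (l, m) not in seen]
        if missing:
            warnings.warn(f"design has unobserved cells: {missing}", stacklevel=2)
        return cls(
            focal_locus=focal_locus,
            backgrounds=backgrounds,
            cell_map=cell_map,
            background_states=bg_states_by_label,
            missing_cells=missing,
        )


def _mutant_state(focal_locus: str) -> str:
    return "lc" if focal_locus == "wus" else "null"
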