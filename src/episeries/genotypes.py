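"""Three-locus genotype labels for the CLV3 promoter allelic-series designs.

A genotype is identified by the state of three loci in the tomato stem-cell
circuit: the *SlCLV3* promoter allele (an open set of labels, ``"WT"``,
``"fas"``, ``"Pro-2"``, ...), the *SlWUS* cis-regulatory state (``"WT"`` or
``"lc"``), and the *SlCLE9* coding state (``"WT"`` or ``"null"``).
"""

from __future__ import annotations

from dataclasses import dataclass

WUS_STATES = ("WT", "lc")
CLE9_STATES = ("WT", "null")

_ID_SEP = "|"


@dataclass(frozen=True, order=True)
class LocusState:
    """State of the three loci; equality is field-wise."""

    clv3_allele: str
    wus: str = "WT"
    cle9: str = "WT"

    def __post_init__(self) -> None:
        if not self.clv3_allele or not isinstance(self.clv3_allele, str):
            raise ValueError("clv3_allele must be a non-empty string")
        if _ID_SEP in self.clv3_allele:
            raise ValueError(f"clv3_allele may not contain {_ID_SEP!r}")
        if self.wus not in WUS_STATES:
            raise ValueError(f"wus must be one of {WUS_STATES}, got {self.wus!r}")
        if self.cle9 not in CLE9_STATES:
            raise ValueError(f"cle9 must be one of {CLE9_STATES}, got {self.cle9!r}")


@dataclass(frozen=True, order=True)
class Genotype:
    """A three-locus genotype; two genotypes are equal iff all locus states are."""

    loci: LocusState

    @property
    def genotype_id(self) -> str:
        """Canonical string id, round-trips through :meth:`from_id`."""
        s = self.loci
        return _ID_SEP.join((s.clv3_allele, s.wus, s.cle9))

    @classmethod
    def from_states(cls, clv3_allele: str, wus: str = "WT", cle9: str = "WT") -> "Genotype":
        return cls(LocusState(clv3_allele, wus, cle9))

    @classmethod
    def from_id(cls, genotype_id: str) -> "Genotype":
        parts = genotype_id.split(_ID_SEP)
        if len(parts) != 3:
            raise ValueError(f"malformed genotype id: {genotype_id!r}")
        return cls(LocusState(*parts))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.genotype_id
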