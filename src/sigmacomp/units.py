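"""Cell geometry and unit conversion between molecule counts and molar concentrations.

The model's canonical internal unit is molar: dissociation constants are molar
quantities, while the literature reports RNA polymerase and sigma factor
abundances as copies per cell.  :class:`CellContext` owns the conversion
``n = C * N_A * V`` for a cell of volume ``V`` (default 1.32 fL, an average
rapidly growing E. coli cell) and the bookkeeping of non-specific genomic
binding sites (default 3.8 genome equivalents of a 4.6 Mbp chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DomainError

AVOGADRO = 6.02214076e23
GENOME_BP = 4.6e6
GENOME_EQUIVALENTS = 3.8

#: Default number of non-specific DNA binding sites per cell (one per base pair).
DEFAULT_NS_SITES = GENOME_EQUIVALENTS * GENOME_BP


@dataclass(frozen=True)
class CellContext:
    """Cell volume and non-specific-site bookkeeping.

    Parameters
    ----------
    volume_fl:
        Cell volume in femtoliters.
    ns_sites:
        Number of non-specific DNA binding sites per cell (dimensionless count).
    unit_mode:
        ``"counts"`` or ``"molar"``; selects the reporting unit of solved
        states.  Internal computation is always molar.
    """

    volume_fl: float = 1.32
    ns_sites: float = DEFAULT_NS_SITES
    unit_mode: str = "counts"

    def __post_init__(self) -> None:
        if not self.volume_fl > 0:
            raise DomainError(f"argument 'volume_fl' must be > 0, got {self.volume_fl!r}")
        if self.ns_sites < 0:
            raise DomainError(f"argument 'ns_sites' must be >= 0, got {self.ns_sites!r}")
        if self.unit_mode not in ("counts", "molar"):
            raise DomainError(f"unit_mode must be 'counts' or 'molar', got {self.unit_mode!r}")

    @property
    def volume_l(self) -> float:
        return self.volume_fl * 1e-15

    @property
    def counts_per_molar(self) -> float:
        """Molecules per cell corresponding to a 1 M concentration."""
        return AVOGADRO * self.volume_l

    def counts_to_molar(self, n: float) -> float:
        return n / self.counts_per_molar

    def molar_to_counts(self, c: float) -> float:
        return c * self.counts_per_molar

    @property
    def ns_sites_molar(self) -> float:
        """Concentration of non-specific binding sites, D, in molar."""
        return self.counts_to_molar(self.ns_sites)


#: Context whose count unit IS molar (counts_per_molar == 1): lets the cell-based
#: solvers run directly on in-vitro assay concentrations with no DNA present.
MOLAR_CONTEXT = CellContext(volume_fl=1e15 / AVOGADRO, ns_sites=0.0,
                            unit_mode="molar")
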