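"""Promoter occupancy and transcription rates.

Initiation is a Michaelis-Menten function of the free cognate holoenzyme
concentration h: rate = kmax * [P] * h / (K_M + h).  The Michaelis constant
coincides with the holoenzyme-promoter dissociation constant when binding
equilibrates before initiation; more detailed multi-step initiation schemes
map onto the same form (see :func:`mm_from_three_state`).  Promoters bound,
but not transcribed, by a second holoenzyme species are repressed through
standard competitive single-site occupancy.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .errors import ConfigError, check_nonnegative, check_positive
from .species import PromoterClass
from .units import CellContext


def promoter_conc(promoter: PromoterClass, context: CellContext) -> float:
    """[P_g] in molar for a promoter class."""
    return context.counts_to_molar(promoter.count)


def occupancy(holo_free: float, promoter: PromoterClass,
              repressor_free: Mapping[str, float] | None = None) -> float:
    """Fraction of promoters occupied by the cognate holoenzyme.

    With competing non-transcribing holoenzymes r at their repression
    constants K_rep:  theta = (h/K_M) / (1 + h/K_M + sum_r r/K_rep).
    """
    check_nonnegative(holo_free=holo_free)
    load = holo_free / promoter.km
    rep = 0.0
    if promoter.repressors:
        repressor_free = repressor_free or {}
        for label, kd_rep in promoter.repressors:
            if label not in repressor_free:
                raise ConfigError(
                    f"promoter {promoter.name!r}: repressor species {label!r} "
                    "not present in the solved state")
            rep += repressor_free[label] / kd_rep
    return load / (1.0 + load + rep)


def transcription_rate(holo_free: float, promoter: PromoterClass,
                       context: CellContext | None = None) -> float:
    """RNA synthesis rate per volume (M/s): kmax * [P_g] * h / (K_M + h)."""
    check_nonnegative(holo_free=holo_free)
    context = context or CellContext()
    return (promoter.kmax * promoter_conc(promoter, context)
            * holo_free / (promoter.km + holo_free))


def normalized_rate(holo_free: float, promoter: PromoterClass) -> float:
    """Normalized transcription rate per gene: h / (K_M + h), in [0, 1]."""
    check_nonnegative(holo_free=holo_free)
    return holo_free / (promoter.km + holo_free)


def rate_with_repressor(holo_free: float,
                        repressor_free: Mapping[str, float] | float,
                        promoter: PromoterClass,
                        context: CellContext | None = None) -> float:
    """Transcription rate of a promoter also bound by non-transcribing holoenzymes.

    ``repressor_free`` maps repressor species label to its free holoenzyme
    concentration (molar); a bare float is accepted when the promoter lists a
    single repressor.  Reduces to :func:`transcription_rate` when all
    repressor concentrations are zero, and represses even saturated promoters
    because the repressor competes for the promoter itself, not for core.
    """
    check_nonnegative(holo_free=holo_free)
    if not promoter.repressors:
        raise ConfigError(f"promoter {promoter.name!r} has no repressors configured")
    if not isinstance(repressor_free, Mapping):
        if len(promoter.repressors) != 1:
            raise ConfigError(
                f"promoter {promoter.name!r} lists {len(promoter.repressors)} "
                "repressors; pass a mapping of concentrations")
        repressor_free = {promoter.repressors[0][0]: float(repressor_free)}
    for value in repressor_free.values():
        check_nonnegative(repressor_free=value)
    context = context or CellContext()
    theta = occupancy(holo_free, promoter, repressor_free)
    return promoter.kmax * promoter_conc(promoter, context) * theta


def mm_from_three_state(kon_p: float, koff_p: float, kinit: float
                        ) -> tuple[float, float]:
    """Map the scheme  H + P <-> HP -> initiation  to Michaelis-Menten form.

    Returns ``(K_M, kmax) = ((koff_p + kinit) / kon_p, kinit)``.  When
    initiation is slow relative to promoter unbinding (kinit << koff_p) the
    Michaelis constant approaches the equilibrium promoter dissociation
    constant koff_p / kon_p, which is why slowly firing, strongly binding
    promoters sit saturated and insulated from sigma factor competition.
    """
    check_positive(kon_p=kon_p, kinit=kinit)
    check_nonnegative(koff_p=koff_p)
    return (koff_p + kinit) / kon_p, kinit
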