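"""Trait schemes: named traits, their modalities, and drying-resistance flags.

A *trait* (e.g. locomotion mode) is described by several *modalities*
(e.g. crawler, burrower).  Fuzzy coding gives every taxon an affinity for
each modality, normalized to sum to 1 within each trait.  A subset of
(trait, modality) pairs can be flagged as conferring resistance or
resilience to drying (small body size, short life span, high fecundity,
dormant stages, ...); the synthetic-data generator uses those flags to
filter taxa along the flow-intermittence gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class SchemeError(ValueError):
    """Raised when a trait scheme violates its structural invariants."""


@dataclass(frozen=True)
class TraitScheme:
    """Ordered trait/modality layout of a fuzzy-coded trait table.

    Parameters
    ----------
    traits
        Ordered trait names.
    modalities
        Mapping trait name -> ordered modality labels (>= 2 each).
    resistance_traits
        (trait, modality) pairs conferring drying resistance/resilience.
    """

    traits: tuple[str, ...]
    modalities: dict[str, tuple[str, ...]]
    resistance_traits: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.traits:
            raise SchemeError("scheme must declare at least one trait")
        if set(self.traits) != set(self.modalities):
            raise SchemeError("traits and modality mapping disagree")
        for trait in self.traits:
            mods = self.modalities[trait]
            if len(mods) < 2:
                raise SchemeError(f"trait {trait!r} has fewer than 2 modalities")
            if len(set(mods)) != len(mods):
                raise SchemeError(f"duplicate modality labels within trait {trait!r}")
        for trait, mod in self.resistance_traits:
            if trait not in self.modalities or mod not in self.modalities[trait]:
                raise SchemeError(f"resistance flag ({trait!r}, {mod!r}) not in scheme")

    @property
    def columns(self) -> list[tuple[str, str]]:
        """Flat (trait, modality) column order of the trait table."""
        return [(t, m) for t in self.traits for m in self.modalities[t]]

    @property
    def n_columns(self) -> int:
        return sum(len(self.modalities[t]) for t in self.traits)

    def block_slices(self) -> dict[str, slice]:
        """Column slice of each trait's modality block."""
        out: dict[str, slice] = {}
        start = 0
        for trait in self.traits:
            stop = start + len(self.modalities[trait])
            out[trait] = slice(start, stop)
            start = stop
        return out

    def resistance_column_indices(self) -> list[int]:
        cols = self.columns
        return [cols.index(pair) for pair in self.resistance_traits]


def default_scheme() -> TraitScheme:
    """Twelve biological traits typical of macroinvertebrate databases.

    Modalities marked as resistance/resilience follow habitat-templet
    expectations for drying: small maximal size, short life span, high
    fecundity, plurivoltinism, dormant or desiccation-resistant stages,
    aerial respiration, burrowing, and aerial dispersal.
    """
    modalities = {
        "max_size": ("small", "medium", "large"),
        "life_span": ("short", "long"),
        "voltinism": ("semivoltine", "univoltine", "plurivoltine"),
        "fecundity": ("low", "medium", "high"),
        "resistance_form": ("eggs", "cocoons", "diapause", "none"),
        "respiration": ("tegument", "gill", "spiracle", "plastron"),
        "locomotion": ("flier", "swimmer", "crawler", "burrower", "interstitial"),
        "dispersal": ("aquatic_passive", "aquatic_active", "aerial_passive", "aerial_active"),
        "reproduction": ("isolated_eggs", "clutches", "asexual"),
        "food": ("detritus", "plants", "animals", "microorganisms"),
        "feeding_habit": ("deposit_feeder", "shredder", "scraper", "filter_feeder", "predator"),
        "aquatic_stage": ("egg", "larva", "nymph", "adult"),
    }
    resistance = (
        ("max_size", "small"),
        ("life_span", "short"),
        ("voltinism", "plurivoltine"),
        ("fecundity", "high"),
        ("resistance_form", "eggs"),
        ("resistance_form", "cocoons"),
        ("resistance_form", "diapause"),
        ("respiration", "spiracle"),
        ("respiration", "plastron"),
        ("locomotion", "burrower"),
        ("locomotion", "interstitial"),
        ("dispersal", "aerial_active"),
    )
    return TraitScheme(
        traits=tuple(modalities),
        modalities={k: tuple(v) for k, v in modalities.items()},
        resistance_traits=resistance,
    )
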