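"""Neocortical cell-type taxonomy at subclass resolution.

The reference taxonomy distinguishes 19 subclasses: 5 GABAergic interneuron
subclasses (named by marker genes), 7 glutamatergic pyramidal subclasses
(named by layer and projection pattern), and 7 non-neuronal subclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GABAERGIC = ("LAMP5", "PAX6", "SST", "VIP", "PVALB")
GLUTAMATERGIC = ("IT", "L4 IT", "L5 6 IT Car3", "L5 6 NP", "L5 ET", "L6 CT", "L6b")
NON_NEURONAL = (
    "Astrocyte",
    "Oligodendrocyte",
    "OPC",
    "Microglia",
    "Endothelial",
    "Pericyte",
    "VLMC",
)


@dataclass(frozen=True)
class Taxonomy:
    """Ordered subclass labels plus a subclass -> class map."""

    subclasses: tuple[str, ...]
    class_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if len(self.subclasses) != len(set(self.subclasses)):
            raise ValueError("subclass labels must be unique")
        missing = [s for s in self.subclasses if s not in self.class_of]
        if missing:
            raise ValueError(f"class_of missing subclasses: {missing}")

    @property
    def n_subclasses(self) -> int:
        return len(self.subclasses)

    def of_class(self, cls: str) -> tuple[str, ...]:
        return tuple(s for s in self.subclasses if self.class_of[s] == cls)


def default_taxonomy() -> Taxonomy:
    """The 19-subclass human neocortical taxonomy used throughout."""
    subclasses = GABAERGIC + GLUTAMATERGIC + NON_NEURONAL
    class_of = {s: "GABAergic" for s in GABAERGIC}
    class_of.update({s: "glutamatergic" for s in GLUTAMATERGIC})
    class_of.update({s: "non-neuronal" for s in NON_NEURONAL})
    return Taxonomy(subclasses=subclasses, class_of=class_of)
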