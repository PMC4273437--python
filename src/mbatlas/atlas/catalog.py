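"""Canonical compartment and subdivision catalog for the mushroom-body lobes.

The lobes are tiled by 15 compartments (5 per lobe: γ1–γ5, β′1–β′2 + α′1–α′3,
β1–β2 + α1–α3) plus the core of the distal pedunculus (``pedc``).  Each
compartment intersects the axon layers of specific Kenyon-cell (KC) types,
yielding 37 elemental subdivisions ("synaptic units"): the smallest lobe
regions where a fixed set of MBONs, DANs and KC types overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

__all__ = ["Subdivision", "SubdivisionCatalog", "default_catalog"]

#: the 15 compartments in canonical order (pedc is kept separate)
COMPARTMENTS = (
    "g1", "g2", "g3", "g4", "g5",
    "bp1", "bp2", "b1", "b2",
    "ap1", "ap2", "ap3", "a1", "a2", "a3",
)

#: KC-layer tags carried by each compartment
COMPARTMENT_LAYERS = {
    **{c: ("d", "main") for c in ("g1", "g2", "g3", "g4", "g5")},
    "bp1": ("ap", "m"),
    "bp2": ("a", "m", "p"),
    **{c: ("ap", "m") for c in ("ap1", "ap2", "ap3")},
    **{c: ("p", "s", "c") for c in ("b1", "b2", "a1", "a2", "a3")},
}

#: the seven KC types with per-hemisphere cell counts printed in the atlas
KC_COUNTS = {
    "gd": 75, "gmain": 600,
    "apbpap": 210, "apbpm": 140,
    "abp": 90, "abs": 500, "abc": 400,
}

# which KC type's axons fill each layer tag, per lobe family
_KC_BY_LAYER = {
    ("g", "d"): "gd", ("g", "main"): "gmain",
    ("apbp", "ap"): "apbpap", ("apbp", "m"): "apbpm",
    # single α′/β′ap axons branch to both the anterior and posterior β′2 layers
    ("apbp", "a"): "apbpap", ("apbp", "p"): "apbpap",
    ("ab", "p"): "abp", ("ab", "s"): "abs", ("ab", "c"): "abc",
}

_LOBE_FAMILY = {"g": "g", "bp": "apbp", "ap": "apbp", "b": "ab", "a": "ab"}


@dataclass(frozen=True)
class Subdivision:
    id: str            # e.g. "a2s"; "g1main" spells out the γ main layer
    compartment: str   # e.g. "a2", or "pedc"
    layer: str         # KC-layer tag, "" for pedc
    kc_types: frozenset[str]  # KC types whose axons occupy it


class SubdivisionCatalog:
    """Ordered enumeration of compartments and elemental subdivisions."""

    def __init__(self) -> None:
        subs: list[Subdivision] = []
        for comp in COMPARTMENTS:
            family = _LOBE_FAMILY["bp" if comp.startswith("bp")
                                  else "ap" if comp.startswith("ap")
                                  else comp[0]]
            for layer in COMPARTMENT_LAYERS[comp]:
                kc = _KC_BY_LAYER[(family, layer)]
                subs.append(
                    Subdivision(comp + layer, comp, layer, frozenset({kc}))
                )
        # the pedc intersects the bundled axons of all three α/β KC types
        subs.append(
            Subdivision("pedc", "pedc", "", frozenset({"abp", "abs", "abc"}))
        )
        self.subdivisions: tuple[Subdivision, ...] = tuple(subs)
        self._by_id = {s.id: s for s in subs}

    @property
    def compartments(self) -> tuple[str, ...]:
        return COMPARTMENTS

    @property
    def subdivision_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.subdivisions)

    def __len__(self) -> int:
        return len(self.subdivisions)

    def __contains__(self, region: str) -> bool:
        return region in self._by_id or region in COMPARTMENTS

    def kc_layer_occupancy(self, subdivision: str) -> frozenset[str]:
        """KC types whose axons occupy one elemental subdivision."""
        return self._by_id[subdivision].kc_types

    def expand(self, regions) -> frozenset[str]:
        """Resolve mixed compartment/subdivision ids to subdivision ids.

        A bare compartment id expands to all of its subdivisions; subdivision
        ids (and ``pedc``) pass through.  Unknown ids raise ``KeyError``.
        """
        out: set[str] = set()
        for r in regions:
            if r in self._by_id:
                out.add(r)
            elif r in COMPARTMENTS:
                out.update(
                    s.id for s in self.subdivisions if s.compartment == r
                )
            else:
                raise KeyError(f"unknown region id {r!r}")
        return frozenset(out)

    def compartments_of(self, regions, *, include_pedc: bool = True) -> frozenset[str]:
        """Map mixed region ids to the compartments they belong to.

        ``include_pedc=False`` restricts the answer to the 15 lobe
        compartments, the convention used when counting how many compartments
        a DAN type terminates in.
        """
        comps: set[str] = set()
        for r in regions:
            comp = r if r in COMPARTMENTS or r == "pedc" else self._by_id[r].compartment
            comps.add(comp)
        if not include_pedc:
            comps.discard("pedc")
        return frozenset(comps)


@lru_cache(maxsize=1)
def default_catalog() -> SubdivisionCatalog:
    return SubdivisionCatalog()
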