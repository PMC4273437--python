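"""Census and graph queries over the cell-type atlas.

These reproduce the atlas' printed arithmetic: per-class cell totals,
compartment-multiplicity histograms, the transmitter census, KC→MBON
convergence ratios, PAM-cluster cell sums, and the depth of the feedforward
network formed by the three MBON types whose axons re-enter the lobes.
"""

from __future__ import annotations

import math

import networkx as nx

from .records import Atlas, load_atlas

__all__ = [
    "total_cells",
    "count_by_compartment_multiplicity",
    "transmitter_census",
    "convergence_ratio",
    "sum_pam_counts",
    "build_feedforward_graph",
    "feedforward_depth",
    "mbons_without_mbon_input",
]

KC_SOURCE = "KC"

#: printed convergence approximations, recorded alongside the derived values
#: (the β2β′2a ratio derives to 2400 from the rounded per-type KC counts and
#: is deliberately not forced to match the printed ~2300)
REPORTED_CONVERGENCE = {"MBON-a2p3p": 90, "MBON-b2bp2a": 2300}


def total_cells(
    cell_class: str,
    atlas: Atlas | None = None,
    *,
    use: str = "min",
    round_to: int | None = None,
) -> int:
    """Sum per-hemisphere cell counts over the types of one class.

    Count ranges contribute their minimum unless ``use="max"``.
    ``round_to=100`` rounds the sum to the nearest hundred (the convention
    for quoting the ~2000 KCs whose per-type counts sum to 2015).
    """
    atlas = atlas or load_atlas()
    idx = 0 if use == "min" else 1
    total = sum(r.cells_per_hemisphere[idx] for r in atlas.of_class(cell_class))
    if round_to:
        total = round_to * round(total / round_to)
    return total


def count_by_compartment_multiplicity(
    cell_class: str, atlas: Atlas | None = None
) -> dict[str, int]:
    """Histogram {"1": n, "2+": m} of compartments innervated per type.

    MBON types are counted by dendritic compartments, DAN types by the lobe
    compartments holding their axon terminals.  The pedunculus core counts as
    an extra region for MBON dendrites (a compartment plus the pedc makes a
    type multi-compartment) but not for DAN terminals, which are tallied over
    the 15 lobe compartments only — the convention under which exactly 3 of
    the 20 DAN types reach two compartments.
    """
    atlas = atlas or load_atlas()
    if cell_class == "MBON":
        recs = atlas.of_class("MBON")
        region_sets = [
            atlas.catalog.compartments_of(r.dendrite_regions, include_pedc=True)
            for r in recs
        ]
    elif cell_class in ("DAN", "DAN-PAM", "DAN-PPL1"):
        recs = atlas.of_class(cell_class)
        region_sets = [
            atlas.catalog.compartments_of(r.axon_regions_in_lobes, include_pedc=False)
            for r in recs
        ]
    else:
        raise KeyError(f"multiplicity is defined for MBON/DAN classes, not {cell_class!r}")
    hist = {"1": 0, "2+": 0}
    for regions in region_sets:
        if len(regions) >= 2:
            hist["2+"] += 1
        elif len(regions) == 1:
            hist["1"] += 1
    return hist


def transmitter_census(cell_class: str, atlas: Atlas | None = None) -> dict[str, int]:
    """Number of cell types (not cells) per putative transmitter."""
    atlas = atlas or load_atlas()
    census: dict[str, int] = {}
    for r in atlas.of_class(cell_class):
        census[r.transmitter] = census.get(r.transmitter, 0) + 1
    return census


def convergence_ratio(mbon_name: str, atlas: Atlas | None = None) -> int:
    """KC→MBON convergence: distinct KCs presynaptic to one MBON type.

    Assumes every KC forms synapses in each elemental subdivision its axon
    passes through, so the answer is the summed count of KC types whose
    layers intersect the MBON's dendritic subdivisions, doubled for MBONs
    with bilateral dendrites.
    """
    atlas = atlas or load_atlas()
    rec = atlas[mbon_name]
    if rec.cell_class != "MBON":
        raise KeyError(f"{mbon_name!r} is not an MBON type")
    subs = atlas.catalog.expand(rec.dendrite_regions)
    kc_types: set[str] = set()
    for s in subs:
        kc_types |= atlas.catalog.kc_layer_occupancy(s)
    from .catalog import KC_COUNTS

    n = sum(KC_COUNTS[k] for k in kc_types)
    return 2 * n if rec.bilateral_dendrites else n


def sum_pam_counts(source: str, atlas: Atlas | None = None) -> int | float:
    """Total PAM-cluster DANs by summing the nine per-compartment counts.

    ``source`` is ``"split_gal4"`` or ``"pa_gfp"``; photoactivation counts
    are means and their sum is rounded half-away-from-zero to whole cells.
    """
    atlas = atlas or load_atlas()
    if source not in ("split_gal4", "pa_gfp"):
        raise KeyError(f"unknown count source {source!r}")
    table = atlas.pam_counts[source]
    missing = [c for c in atlas.pam_counts["compartments"] if c not in table]
    if missing:
        raise KeyError(f"missing PAM compartment entries: {missing}")
    total = sum(table[c] for c in atlas.pam_counts["compartments"])
    if source == "pa_gfp":
        return int(math.floor(total + 0.5)) if total >= 0 else int(math.ceil(total - 0.5))
    return total


def build_feedforward_graph(atlas: Atlas | None = None) -> nx.DiGraph:
    """Directed MBON graph derived from the innervation matrix.

    The KC source node feeds every MBON; an MBON→MBON edge exists wherever a
    source type's in-lobe axon subdivisions intersect a target type's
    dendritic subdivisions.  The MBON part must be acyclic (information flows
    one way through the lobes); a cycle raises ``ValueError``.
    """
    atlas = atlas or load_atlas()
    g = nx.DiGraph()
    g.add_node(KC_SOURCE)
    mbons = atlas.of_class("MBON")
    dend = {r.name: atlas.matrix.dendrite_subdivisions(r.name) for r in mbons}
    term = {r.name: atlas.matrix.terminal_subdivisions(r.name) for r in mbons}
    for r in mbons:
        g.add_node(r.name)
        g.add_edge(KC_SOURCE, r.name)
    for src in mbons:
        if not term[src.name]:
            continue
        own = atlas.catalog.compartments_of(dend[src.name])
        for tgt in mbons:
            if term[src.name] & dend[tgt.name]:
                hit = atlas.catalog.compartments_of(term[src.name] & dend[tgt.name])
                if hit & own:
                    raise ValueError(
                        f"{src.name}: axon terminals re-enter its own dendritic "
                        f"compartment(s) {sorted(hit & own)}"
                    )
                g.add_edge(src.name, tgt.name)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"MBON feedforward graph has a cycle: {cycle}")
    return g


def feedforward_depth(atlas: Atlas | None = None) -> int:
    """Maximum number of MBON layers on any directed path from the KCs."""
    g = build_feedforward_graph(atlas)
    # longest path in the DAG, counted in MBON nodes (the KC source excluded)
    return nx.dag_longest_path_length(g)


def mbons_without_mbon_input(atlas: Atlas | None = None) -> tuple[str, ...]:
    """MBON types reading out KC activity only (no MBON→MBON in-edge)."""
    g = build_feedforward_graph(atlas)
    return tuple(
        n for n in g.nodes
        if n != KC_SOURCE
        and all(p == KC_SOURCE for p in g.predecessors(n))
    )
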