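"""The packaged cell-type atlas: records, fixtures and the innervation matrix.

The atlas ships as three versioned fixture files under ``data/``:

* ``cell_types.csv`` — one row per cell type (KCs, MBONs, DANs, other
  modulatory neurons) with per-hemisphere cell counts, putative transmitter
  and the lobe regions derived from the systematic nomenclature;
* ``innervation_matrix.csv`` — cell types × 37 elemental subdivisions with
  entry codes ``N`` (none), ``Dd``/``Ds`` (dense/sparse dendrites),
  ``Xd``/``Xs`` (dense/sparse axon terminals) and ``O`` (in-lobe dendrites of
  the one DAN type that has them);
* ``pam_counts.json`` — per-compartment counts of PAM-cluster DANs from
  split-GAL4 labeling and from photoactivation tracing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .catalog import SubdivisionCatalog, default_catalog
from .names import parse_cell_type_name

__all__ = [
    "CellTypeRecord",
    "InnervationMatrix",
    "Atlas",
    "load_atlas",
    "CELL_CLASSES",
    "TRANSMITTERS",
]

CELL_CLASSES = ("KC", "MBON", "DAN-PAM", "DAN-PPL1", "other-modulatory")
TRANSMITTERS = (
    "acetylcholine", "glutamate", "GABA", "dopamine",
    "octopamine", "serotonin", "peptide", "unknown",
)

#: entry codes of the innervation matrix
ENTRY_CODES = ("N", "Dd", "Ds", "Xd", "Xs", "O")
DENDRITE_CODES = frozenset({"Dd", "Ds"})
TERMINAL_CODES = frozenset({"Xd", "Xs"})


@dataclass(frozen=True)
class CellTypeRecord:
    """One atlas row; region fields hold canonical ASCII region ids."""

    name: str
    display_name: str
    short_name: str
    cell_class: str
    cells_per_hemisphere: tuple[int, int]  # (min, max)
    transmitter: str
    dendrite_regions: frozenset[str] = field(default_factory=frozenset)
    axon_regions_in_lobes: frozenset[str] = field(default_factory=frozenset)
    extralobe_projection_zones: frozenset[str] = field(default_factory=frozenset)
    bilateral_dendrites: bool = False
    count_note: str = ""
    notes: str = ""

    def validate(self, catalog: SubdivisionCatalog, neuropil_ids: frozenset[str]) -> None:
        lo, hi = self.cells_per_hemisphere
        if not (1 <= lo <= hi):
            raise ValueError(f"{self.name}: bad cell count range {lo}..{hi}")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"{self.name}: unknown class {self.cell_class!r}")
        if self.transmitter not in TRANSMITTERS:
            raise ValueError(f"{self.name}: unknown transmitter {self.transmitter!r}")
        for r in self.dendrite_regions | self.axon_regions_in_lobes:
            if r not in catalog:
                raise ValueError(f"{self.name}: region {r!r} not in catalog")
        bad = self.extralobe_projection_zones - neuropil_ids
        if bad:
            raise ValueError(f"{self.name}: unknown neuropil ids {sorted(bad)}")
        if self.cell_class == "MBON" and not self.dendrite_regions:
            raise ValueError(f"{self.name}: MBON with empty dendrite regions")
        if self.cell_class.startswith("DAN") and not self.axon_regions_in_lobes:
            raise ValueError(f"{self.name}: DAN with empty terminal regions")


class InnervationMatrix:
    """Cell types × elemental subdivisions with polarity-coded entries."""

    def __init__(self, rows: dict[str, dict[str, str]], catalog: SubdivisionCatalog):
        self.catalog = catalog
        self.cols = catalog.subdivision_ids
        self.rows = rows
        for name, entries in rows.items():
            for sub, code in entries.items():
                if sub not in self.cols:
                    raise ValueError(f"{name}: unknown subdivision {sub!r}")
                if code not in ENTRY_CODES:
                    raise ValueError(f"{name}: unknown entry code {code!r}")

    def entry(self, name: str, subdivision: str) -> str:
        return self.rows[name].get(subdivision, "N")

    def dendrite_subdivisions(self, name: str) -> frozenset[str]:
        return frozenset(
            s for s, c in self.rows[name].items() if c in DENDRITE_CODES
        )

    def terminal_subdivisions(self, name: str) -> frozenset[str]:
        return frozenset(
            s for s, c in self.rows[name].items() if c in TERMINAL_CODES
        )

    def inlobe_dan_dendrites(self, name: str) -> frozenset[str]:
        return frozenset(s for s, c in self.rows[name].items() if c == "O")


@dataclass(frozen=True)
class Atlas:
    """The loaded atlas fixture set."""

    records: tuple[CellTypeRecord, ...]
    matrix: InnervationMatrix
    catalog: SubdivisionCatalog
    neuropil_regions: tuple[str, ...]
    mbon_projection_zones: tuple[str, ...]
    pam_counts: dict

    def __getitem__(self, name: str) -> CellTypeRecord:
        for r in self.records:
            if r.name == name or r.display_name == name:
                return r
        raise KeyError(name)

    def of_class(self, cell_class: str) -> tuple[CellTypeRecord, ...]:
        """Records of one class; ``"DAN"`` selects both PAM and PPL1."""
        if cell_class == "DAN":
            wanted = ("DAN-PAM", "DAN-PPL1")
        elif cell_class in CELL_CLASSES:
            wanted = (cell_class,)
        else:
            raise KeyError(f"unknown cell class {cell_class!r}")
        return tuple(r for r in self.records if r.cell_class in wanted)


def _split_regions(cell: str) -> frozenset[str]:
    return frozenset(cell.split()) if cell.strip() else frozenset()


def _read_text(filename: str) -> str:
    return (
        resources.files("mbatlas.atlas").joinpath("data").joinpath(filename).read_text("utf-8")
    )


@lru_cache(maxsize=1)
def load_atlas(validate: bool = True) -> Atlas:
    """Load and cross-validate the packaged fixtures."""
    catalog = default_catalog()
    neuro = json.loads(_read_text("neuropils.json"))
    neuropil_ids = frozenset(neuro["regions"])
    records = []
    for row in csv.DictReader(_read_text("cell_types.csv").splitlines()):
        records.append(
            CellTypeRecord(
                name=row["name"],
                display_name=row["display_name"],
                short_name=row["short_name"],
                cell_class=row["cell_class"],
                cells_per_hemisphere=(int(row["cells_min"]), int(row["cells_max"])),
                transmitter=row["transmitter"],
                dendrite_regions=_split_regions(row["dendrite_regions"]),
                axon_regions_in_lobes=_split_regions(row["axon_regions_in_lobes"]),
                extralobe_projection_zones=_split_regions(row["extralobe_zones"]),
                bilateral_dendrites=row["bilateral_dendrites"] == "True",
                count_note=row["count_note"],
                notes=row["notes"],
            )
        )
    rows: dict[str, dict[str, str]] = {}
    for row in csv.DictReader(_read_text("innervation_matrix.csv").splitlines()):
        name = row.pop("name")
        rows[name] = {sub: code for sub, code in row.items() if code != "N"}
    matrix = InnervationMatrix(rows, catalog)
    atlas = Atlas(
        records=tuple(records),
        matrix=matrix,
        catalog=catalog,
        neuropil_regions=tuple(neuro["regions"]),
        mbon_projection_zones=tuple(neuro["mbon_projection_zones"]),
        pam_counts=json.loads(_read_text("pam_counts.json")),
    )
    if validate:
        _validate(atlas)
    return atlas


def _validate(atlas: Atlas) -> None:
    neuropil_ids = frozenset(atlas.neuropil_regions)
    for rec in atlas.records:
        rec.validate(atlas.catalog, neuropil_ids)
        # nomenclature round-trip: the systematic name encodes the region sets
        if rec.cell_class in ("MBON", "DAN-PAM", "DAN-PPL1"):
            parsed = parse_cell_type_name(rec.name)
            if parsed.dendrite_regions != rec.dendrite_regions:
                raise ValueError(f"{rec.name}: dendrite regions disagree with name")
            if parsed.axon_regions_in_lobes != rec.axon_regions_in_lobes:
                raise ValueError(f"{rec.name}: axon regions disagree with name")
    for rec in atlas.records:
        if rec.cell_class == "MBON":
            if not atlas.matrix.dendrite_subdivisions(rec.name):
                raise ValueError(f"{rec.name}: MBON matrix row has no dendrite entry")
        elif rec.cell_class.startswith("DAN"):
            if not atlas.matrix.terminal_subdivisions(rec.name):
                raise ValueError(f"{rec.name}: DAN matrix row has no terminal entry")
    for name in atlas.matrix.rows:
        if atlas.matrix.inlobe_dan_dendrites(name) and name != "PAM-g4<g1g2":
            raise ValueError(f"'O' entries are only valid for PAM-g4<g1g2, not {name}")
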