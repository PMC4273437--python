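"""Nomenclature for mushroom-body extrinsic neurons.

Cell types are named after the lobe compartments they innervate: an MBON name
lists the compartments (or finer Kenyon-cell-layer subdivisions) containing its
dendrites, optionally followed by ``>`` and the compartments receiving its
in-lobe axon terminals; a DAN name (PAM-/PPL1- prefix) lists its terminal
compartments, optionally followed by ``<`` and its in-lobe dendritic
compartments.

Greek letters and primes are normalized to an ASCII canonical form so fixture
files are encoding-safe::

    gamma -> g      alpha -> a      beta -> b
    alpha' -> ap    beta' -> bp     pedunculus core -> pedc

e.g. ``MBON-γ1pedc>α/β`` <-> ``MBON-g1pedc>ab``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "NameParseError",
    "ParsedName",
    "to_ascii",
    "to_display",
    "parse_cell_type_name",
]

# order matters: primed letters must be replaced before their plain forms
_GREEK_TO_ASCII = [
    ("α′", "ap"), ("β′", "bp"), ("α'", "ap"), ("β'", "bp"),
    ("γ", "g"), ("α", "a"), ("β", "b"), ("´", ""), ("/", ""),
]

# compartment -> display form, in canonical order (15 compartments + pedc)
COMPARTMENT_DISPLAY = {
    "g1": "γ1", "g2": "γ2", "g3": "γ3", "g4": "γ4", "g5": "γ5",
    "bp1": "β′1", "bp2": "β′2", "b1": "β1", "b2": "β2",
    "ap1": "α′1", "ap2": "α′2", "ap3": "α′3",
    "a1": "α1", "a2": "α2", "a3": "α3",
    "pedc": "pedc",
}

# valid Kenyon-cell layer tags per compartment (see catalog module)
_LAYERS = {
    "g": ("d",),            # γ compartments: dorsal layer (main is implicit)
    "bp1": ("ap", "m"),
    "bp2": ("a", "m", "p"),
    "b": ("p", "s", "c"),
    "ap": ("ap", "m"),
    "a": ("p", "s", "c"),
}

_LOBE_SPAN = {
    "g": ("g1", "g2", "g3", "g4", "g5"),
    "bp": ("bp1", "bp2"),
    "b": ("b1", "b2"),
    "ap": ("ap1", "ap2", "ap3"),
    "a": ("a1", "a2", "a3"),
}


class NameParseError(ValueError):
    """Raised for a malformed cell-type name; the message names the token."""


@dataclass(frozen=True)
class ParsedName:
    """Region sets extracted from a systematic cell-type name.

    ``dendrite_regions`` and ``axon_regions_in_lobes`` contain ASCII region
    ids at the granularity the name states: bare compartments (``b1``),
    layer subdivisions (``a2s``), or ``pedc``.
    """

    name: str
    cell_class: str  # "MBON", "DAN-PAM" or "DAN-PPL1"
    dendrite_regions: frozenset[str] = field(default_factory=frozenset)
    axon_regions_in_lobes: frozenset[str] = field(default_factory=frozenset)


def to_ascii(name: str) -> str:
    """Normalize a (possibly Greek) cell-type name to canonical ASCII."""
    s = name
    for greek, ascii_ in _GREEK_TO_ASCII:
        s = s.replace(greek, ascii_)
    return s


def to_display(region: str) -> str:
    """ASCII region id -> display form (``bp2a`` -> ``β′2a``)."""
    if region in COMPARTMENT_DISPLAY:
        return COMPARTMENT_DISPLAY[region]
    m = re.match(r"^(g\d|bp\d|ap\d|b\d|a\d)(.+)$", region)
    if m and m.group(1) in COMPARTMENT_DISPLAY:
        return COMPARTMENT_DISPLAY[m.group(1)] + m.group(2)
    return region


def _tokenize_regions(s: str, context: str) -> list[str]:
    """Turn a run of region characters into a list of region ids.

    Yields compartment ids for un-suffixed tokens (``b2``), subdivision ids
    when layer tags follow (``a2s``, ``a2c`` for ``a2sc``), expands bare lobe
    letters (``a`` -> α1..α3), and recognizes ``ped``/``pedc``.
    """
    out: list[str] = []
    i = 0
    lobe = None
    while i < len(s):
        if s.startswith("pedc", i):
            out.append("pedc")
            i += 4
            continue
        if s.startswith("ped", i):
            out.append("pedc")
            i += 3
            continue
        if s[i].isdigit() and lobe is not None:
            pass  # continuation within the same lobe, e.g. "a2p3p"
        elif s[i] in "ab" and i + 1 < len(s) and s[i + 1] == "p" and (
            i + 2 >= len(s) or s[i + 2].isdigit()
        ):
            lobe = s[i] + "p"
            i += 2
        elif s[i] in "abg":
            lobe = s[i]
            i += 1
        else:
            raise NameParseError(
                f"unrecognized token {s[i:]!r} at position {i} in {context!r}"
            )
        if i >= len(s) or not s[i].isdigit():
            out.extend(_LOBE_SPAN[lobe])  # bare lobe -> all its compartments
            continue
        comp = lobe + s[i]
        i += 1
        if comp not in COMPARTMENT_DISPLAY:
            raise NameParseError(f"unknown compartment {comp!r} in {context!r}")
        layer_set = _LAYERS.get(comp, _LAYERS.get(lobe, ()))
        layers: list[str] = []
        while i < len(s) and not s.startswith("ped", i):
            if "ap" in layer_set and s.startswith("ap", i):
                layers.append("ap")
                i += 2
            elif s[i] in layer_set:
                layers.append(s[i])
                i += 1
            else:
                break
        if layers:
            out.extend(comp + tag for tag in layers)
        else:
            out.append(comp)
    return out


def parse_cell_type_name(name: str) -> ParsedName:
    """Parse a systematic MBON-/PAM-/PPL1- name into its region sets.

    For MBONs the regions before the optional ``>`` are dendritic and those
    after it are in-lobe axon terminals.  For DANs the regions before the
    optional ``<`` are axon terminals and those after it are in-lobe
    dendrites.

    >>> p = parse_cell_type_name("MBON-β1>α")
    >>> sorted(p.dendrite_regions), sorted(p.axon_regions_in_lobes)
    (['b1'], ['a1', 'a2', 'a3'])
    """
    ascii_name = to_ascii(name)
    m = re.match(r"^(MBON|PAM|PPL1)-(.+?)(?:_bilateral)?$", ascii_name)
    if not m:
        raise NameParseError(
            f"name {name!r} lacks an MBON-/PAM-/PPL1- prefix"
        )
    prefix, body = m.group(1), m.group(2)
    cell_class = "MBON" if prefix == "MBON" else f"DAN-{prefix}"
    symbol = None
    if ">" in body:
        symbol = ">"
    if "<" in body:
        if symbol is not None:
            raise NameParseError(f"both '>' and '<' in {name!r}")
        symbol = "<"
    if symbol == ">" and prefix != "MBON":
        raise NameParseError(f"'>' suffix is reserved for MBON names: {name!r}")
    if symbol == "<" and prefix == "MBON":
        raise NameParseError(f"'<' suffix is reserved for DAN names: {name!r}")
    if symbol:
        primary_str, _, suffix_str = body.partition(symbol)
        if not suffix_str:
            raise NameParseError(f"empty region list after {symbol!r} in {name!r}")
    else:
        primary_str, suffix_str = body, ""
    primary = frozenset(_tokenize_regions(primary_str, name))
    suffix = (
        frozenset(_tokenize_regions(suffix_str, name)) if suffix_str else frozenset()
    )
    if prefix == "MBON":
        return ParsedName(name, cell_class, primary, suffix)
    # DANs: leading regions are terminals; "<" introduces in-lobe dendrites
    return ParsedName(name, cell_class, suffix, primary)
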