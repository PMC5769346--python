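"""Lineage-string parsing for QIIME/Greengenes-style taxonomy annotations."""

from __future__ import annotations

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

_PREFIXES = {
    "k__": "kingdom",
    "d__": "kingdom",  # SILVA uses d__ (domain) at the top rank
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}

UNCLASSIFIED = "unclassified"


def parse_lineage(lineage: str | None) -> dict[str, str]:
    """Parse a semicolon-delimited lineage into a rank -> name map.

    Accepts Greengenes-style prefixed ranks (``k__Bacteria; p__Firmicutes``)
    and plain ordered lists (``Bacteria;Firmicutes;...``). Missing or empty
    ranks become ``"unclassified"``.
    """
    out = {rank: UNCLASSIFIED for rank in RANKS}
    if not lineage:
        return out
    fields = [f.strip() for f in str(lineage).split(";")]
    prefixed = any(f[:3] in _PREFIXES for f in fields if len(f) >= 3)
    if prefixed:
        for f in fields:
            if len(f) >= 3 and f[:3] in _PREFIXES:
                name = f[3:].strip()
                if name:
                    out[_PREFIXES[f[:3]]] = name
    else:
        for rank, f in zip(RANKS, fields):
            if f:
                out[rank] = f
    return out


def phylum_of(lineage: str | None) -> str:
    return parse_lineage(lineage)["phylum"]
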