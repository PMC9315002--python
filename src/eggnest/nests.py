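"""Nest character vocabularies and collision-risk recoding.

Three nest characters describe where and how a nest holds its eggs:

* attachment — how the nest is fastened: ``basal`` (supported from below),
  ``lateral/horizontal`` (fastened sideways or to a horizontal fork),
  ``pensile`` (hanging in the air). Risk of egg collision rises with
  looseness of attachment: basal < lateral/horizontal < pensile.
* site — what the nest sits on: ``others`` (ground, cliff, bank, water...),
  ``tree``, ``non-tree vegetation`` (reeds, vines, bushes). Risk rises as
  the substrate becomes less rigid: others < tree < non-tree vegetation.
* structure — the nest's shape: ``scrape/platform`` (open), ``cavity``,
  ``cup``, ``dome`` (enclosed with a small entrance). Risk rises with
  enclosure: scrape/platform < cavity < cup < dome (cavity nests lack the
  rim that defines a cup, so sit below cup on average).

A species recorded with several nest types is assigned the highest-risk
category it uses — the least stable attachment/site or the most enclosed
structure — on the premise that its eggs must withstand the worst case.
"""

from __future__ import annotations

from typing import Iterable, Mapping

__all__ = ["RISK_ORDER", "REFERENCE_LEVELS", "recode_nest_risk",
           "aggregate_level"]

#: category vocabularies in increasing collision-risk order
RISK_ORDER: dict[str, list[str]] = {
    "attachment": ["basal", "lateral/horizontal", "pensile"],
    "site": ["others", "tree", "non-tree vegetation"],
    "structure": ["scrape/platform", "cavity", "cup", "dome"],
}

#: reference (lowest-risk) level of each character for treatment coding
REFERENCE_LEVELS: dict[str, str] = {c: lv[0] for c, lv in RISK_ORDER.items()}

#: level aggregations used by the attachment x site interaction model
AGGREGATIONS: dict[str, dict[str, str]] = {
    "attachment": {"basal": "basal", "lateral/horizontal": "non-basal",
                   "pensile": "non-basal"},
    "site": {"others": "others", "tree": "others",
             "non-tree vegetation": "non-tree vegetation"},
}


def recode_nest_risk(categories: Iterable[str] | str, character: str) -> str:
    """Resolve one species' (possibly multiple) reported nest categories to
    the single highest-risk category of ``character``."""
    if character not in RISK_ORDER:
        raise KeyError(f"unknown nest character {character!r}")
    order = RISK_ORDER[character]
    if isinstance(categories, str):
        categories = [categories]
    cats = list(categories)
    if not cats:
        raise ValueError("no categories supplied")
    for c in cats:
        if c not in order:
            raise ValueError(f"unknown {character} category {c!r}")
    return max(cats, key=order.index)


def aggregate_level(character: str, level: str,
                    mapping: Mapping[str, Mapping[str, str]] = AGGREGATIONS
                    ) -> str:
    """Collapse a level per the interaction-model aggregation (e.g. all
    non-basal attachment types to ``non-basal``)."""
    return mapping[character][level]
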