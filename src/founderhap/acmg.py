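"""ACMG/AMP evidence combining for variant classification.

Implements the published combining-rule table over the standard evidence
codes (PVS1; PS1-4; PM1-6; PP1-5; BA1; BS1-4; BP1-7). Strengths are taken
at their default level (no upgrades or downgrades). When evidence on the
pathogenic and the benign side would each classify on its own — or a
classifying side is accompanied by any tag from the other side — the call
falls back to "uncertain significance" (VUS).

PP5 (reputable-source assertion) is accepted despite its later deprecation;
using it attaches a warning to the result.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["EvidenceTag", "Classification", "parse_tags", "classify", "VOCABULARY"]

_PATHOGENIC_STRENGTHS = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
}
_BENIGN_STRENGTHS = {
    "BA": "stand_alone",
    "BS": "strong",
    "BP": "supporting",
}

VOCABULARY = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)


@dataclass(frozen=True)
class EvidenceTag:
    """One ACMG evidence code with its derived strength and side."""

    code: str
    side: str = field(init=False)       # "pathogenic" | "benign"
    strength: str = field(init=False)

    def __post_init__(self) -> None:
        if self.code not in VOCABULARY:
            raise ValueError(f"unknown ACMG code {self.code!r}")
        for prefix in ("PVS", "PS", "PM", "PP"):
            if self.code.startswith(prefix):
                object.__setattr__(self, "side", "pathogenic")
                object.__setattr__(self, "strength", _PATHOGENIC_STRENGTHS[prefix])
                return
        for prefix in ("BA", "BS", "BP"):
            if self.code.startswith(prefix):
                object.__setattr__(self, "side", "benign")
                object.__setattr__(self, "strength", _BENIGN_STRENGTHS[prefix])
                return


@dataclass(frozen=True)
class Classification:
    value: str       # pathogenic | likely_pathogenic | VUS | likely_benign | benign
    fired_rule: str  # e.g. "P(ii)", "LP(ii)", "none", "conflict"
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"value": self.value, "fired_rule": self.fired_rule,
                "warnings": list(self.warnings)}


def parse_tags(codes: Iterable[str]) -> frozenset[EvidenceTag]:
    return frozenset(EvidenceTag(c.strip()) for c in codes if c.strip())


def _pathogenic_call(pvs: int, ps: int, pm: int, pp: int) -> tuple[str, str]:
    # Pathogenic
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        return "pathogenic", "P(i)"
    if ps >= 2:
        return "pathogenic", "P(ii)"
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return "pathogenic", "P(iii)"
    # Likely pathogenic
    if pvs >= 1 and pm == 1:
        return "likely_pathogenic", "LP(i)"
    if ps == 1 and 1 <= pm <= 2:
        return "likely_pathogenic", "LP(ii)"
    if ps == 1 and pp >= 2:
        return "likely_pathogenic", "LP(iii)"
    if pm >= 3:
        return "likely_pathogenic", "LP(iv)"
    if pm == 2 and pp >= 2:
        return "likely_pathogenic", "LP(v)"
    if pm == 1 and pp >= 4:
        return "likely_pathogenic", "LP(vi)"
    return "VUS", "none"


def _benign_call(ba: int, bs: int, bp: int) -> tuple[str, str]:
    if ba >= 1:
        return "benign", "B(i)"
    if bs >= 2:
        return "benign", "B(ii)"
    if bs == 1 and bp == 1:
        return "likely_benign", "LB(i)"
    if bp >= 2:
        return "likely_benign", "LB(ii)"
    return "VUS", "none"


def classify(tags: Iterable[EvidenceTag | str]) -> Classification:
    """Combine evidence tags into a five-tier classification.

    The outcome is a pure function of the strength multiset; which specific
    code carries a given strength never matters. Reports the combining rule
    that fired.
    """
    tagset = frozenset(t if isinstance(t, EvidenceTag) else EvidenceTag(t) for t in tags)
    warnings = tuple(
        "PP5 is deprecated by ClinGen guidance; treated as ordinary supporting evidence"
        for t in sorted(tagset, key=lambda t: t.code) if t.code == "PP5"
    )
    strengths = Counter((t.side, t.strength) for t in tagset)
    pvs = strengths[("pathogenic", "very_strong")]
    ps = strengths[("pathogenic", "strong")]
    pm = strengths[("pathogenic", "moderate")]
    pp = strengths[("pathogenic", "supporting")]
    ba = strengths[("benign", "stand_alone")]
    bs = strengths[("benign", "strong")]
    bp = strengths[("benign", "supporting")]

    path_value, path_rule = _pathogenic_call(pvs, ps, pm, pp)
    ben_value, ben_rule = _benign_call(ba, bs, bp)
    n_path = pvs + ps + pm + pp
    n_ben = ba + bs + bp

    if path_value != "VUS" and ben_value != "VUS":
        return Classification("VUS", "conflict", warnings)
    if path_value != "VUS":
        if n_ben > 0:
            return Classification("VUS", "conflict", warnings)
        return Classification(path_value, path_rule, warnings)
    if ben_value != "VUS":
        if n_path > 0:
            return Classification("VUS", "conflict", warnings)
        return Classification(ben_value, ben_rule, warnings)
    return Classification("VUS", "none", warnings)
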