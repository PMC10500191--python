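"""Delineate the shared haplotype interval around a focal variant.

With one genotyped carrier per family there is no way to phase STR
genotypes, so sharing is assessed marker-by-marker: a marker is *shared*
when the intersection of the carriers' allele sets is nonempty — a
necessary condition for a common founder haplotype. The minimal shared
region is the run of consecutive shared markers containing the variant
(reported by its outermost shared markers); the maximal region is bounded
by the first discordant marker on each side, or by the map end when no
discordance is found.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .io import GeneticMap, GenotypeRecord

__all__ = ["MarkerSharing", "SharedRegion", "marker_sharing_status",
           "delineate_shared_region", "region_sizes", "sharing_table"]

Status = Literal["shared", "discordant", "uninformative"]


@dataclass(frozen=True)
class MarkerSharing:
    """Sharing status of one marker across the informative carriers."""

    marker: str
    status: Status
    shared_alleles: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if (self.status == "shared") != bool(self.shared_alleles):
            raise ValueError("shared_alleles nonempty iff status == 'shared'")


@dataclass
class SharedRegion:
    """Minimal and maximal shared intervals around the focal variant.

    ``minimal`` names the outermost shared markers flanking the variant
    (``None`` when no shared marker flanks it on both sides).  ``maximal``
    names the first discordant marker on each side; a ``None`` bound means
    the sharing ran to the map end, in which case the corresponding span is
    only a lower bound (``open_left`` / ``open_right``).
    """

    minimal: tuple[str, str] | None
    maximal_left: str | None
    maximal_right: str | None
    per_marker: tuple[MarkerSharing, ...]
    open_left: bool = False
    open_right: bool = False
    variant_terminal: bool = False
    warning: str | None = None
    size_cM_min: float | None = None
    size_cM_max: float | None = None
    size_bp_min: int | None = None
    size_bp_max: int | None = None

    def to_dict(self) -> dict:
        d = {
            "minimal": list(self.minimal) if self.minimal else None,
            "maximal": [self.maximal_left, self.maximal_right],
            "open_ends": [self.open_left, self.open_right],
            "size_cM": {"min": self.size_cM_min, "max": self.size_cM_max},
            "size_bp": {"min": self.size_bp_min, "max": self.size_bp_max},
            "per_marker": [
                {"marker": s.marker, "status": s.status,
                 "shared_alleles": sorted(s.shared_alleles)}
                for s in self.per_marker
            ],
        }
        if self.warning:
            d["warning"] = self.warning
        if self.variant_terminal:
            d["variant_terminal"] = True
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def marker_sharing_status(
    gmap: GeneticMap, genotypes: Sequence[GenotypeRecord], marker: str
) -> MarkerSharing:
    """Sharing status of *marker* over the carrier records.

    Individuals missing at the marker are ignored; fewer than two
    informative carriers makes the marker uninformative (never an error).
    """
    i = gmap.index(marker)
    sets = [g.allele_set(i) for g in genotypes if g.carrier]
    sets = [s for s in sets if s]
    if len(sets) < 2:
        return MarkerSharing(marker, "uninformative")
    common = frozenset.intersection(*sets)
    if common:
        return MarkerSharing(marker, "shared", common)
    return MarkerSharing(marker, "discordant")


def delineate_shared_region(
    gmap: GeneticMap, genotypes: Sequence[GenotypeRecord]
) -> SharedRegion:
    """Delineate minimal and maximal shared intervals around the variant.

    Uninformative markers interposed in a shared run do not break the run
    but can never serve as minimal-interval endpoints. If the markers
    adjacent to the variant are discordant on either side, the minimal
    interval is empty and a warning is set (no exception). Spans are filled
    in by :func:`region_sizes`.
    """
    carriers = [g for g in genotypes if g.carrier]
    if len(carriers) < 2:
        raise ValueError("need at least two carrier records")
    statuses = tuple(
        marker_sharing_status(gmap, carriers, m.name) for m in gmap.markers
    )
    n = len(statuses)
    left_adj = gmap.variant_left_index  # last marker left of variant
    right_adj = left_adj + 1

    def walk(start: int, step: int) -> tuple[int | None, int | None]:
        """Outermost shared index and first discordant index from `start`."""
        outer_shared = None
        j = start
        while 0 <= j < n:
            st = statuses[j].status
            if st == "discordant":
                return outer_shared, j
            if st == "shared":
                outer_shared = j
            j += step
        return outer_shared, None

    left_shared, left_disc = walk(left_adj, -1) if left_adj >= 0 else (None, None)
    right_shared, right_disc = walk(right_adj, +1) if right_adj < n else (None, None)

    minimal = None
    warning = None
    if left_shared is not None and right_shared is not None:
        minimal = (gmap.markers[left_shared].name, gmap.markers[right_shared].name)
    else:
        warning = "no shared marker flanking the variant on both sides; minimal region empty"

    region = SharedRegion(
        minimal=minimal,
        maximal_left=gmap.markers[left_disc].name if left_disc is not None else None,
        maximal_right=gmap.markers[right_disc].name if right_disc is not None else None,
        per_marker=statuses,
        open_left=left_disc is None,
        open_right=right_disc is None,
        variant_terminal=gmap.terminal,
        warning=warning,
    )
    region_sizes(region, gmap)
    return region


def region_sizes(
    region: SharedRegion, gmap: GeneticMap
) -> tuple[float | None, float | None, int | None, int | None]:
    """Fill and return (size_cM_min, size_cM_max, size_bp_min, size_bp_max).

    Map-end sentinels are replaced by the terminal markers for measurement;
    the corresponding ``open_*`` flags mark those spans as lower bounds.
    Physical sizes are omitted (None) when any bound lacks a bp position.
    """

    def spans(left: str | None, right: str | None):
        lm = gmap.marker(left) if left is not None else gmap.markers[0]
        rm = gmap.marker(right) if right is not None else gmap.markers[-1]
        cm = rm.pos_cM - lm.pos_cM
        bp = None
        if lm.pos_bp is not None and rm.pos_bp is not None:
            bp = rm.pos_bp - lm.pos_bp
        return cm, bp

    if region.minimal is not None:
        region.size_cM_min, region.size_bp_min = spans(*region.minimal)
    else:
        region.size_cM_min, region.size_bp_min = 0.0, None
    region.size_cM_max, region.size_bp_max = spans(region.maximal_left, region.maximal_right)
    return (region.size_cM_min, region.size_cM_max, region.size_bp_min, region.size_bp_max)


def sharing_table(region: SharedRegion) -> str:
    """Tab-delimited per-marker sharing table plus a one-line summary."""
    lines = ["marker\tstatus\tshared_alleles"]
    for s in region.per_marker:
        alleles = ",".join(str(a) for a in sorted(s.shared_alleles)) or "."
        lines.append(f"{s.marker}\t{s.status}\t{alleles}")
    mn = "-".join(region.minimal) if region.minimal else "none"
    mx = f"{region.maximal_left or '<map-end'}-{region.maximal_right or 'map-end>'}"
    cm_min = f"{region.size_cM_min:.2f}" if region.size_cM_min is not None else "."
    cm_max = f"{region.size_cM_max:.2f}" if region.size_cM_max is not None else "."
    bp_min = str(region.size_bp_min) if region.size_bp_min is not None else "."
    bp_max = str(region.size_bp_max) if region.size_bp_max is not None else "."
    lines.append(
        f"#region\tminimal={mn} ({cm_min} cM, {bp_min} bp)\t"
        f"maximal={mx} ({cm_max} cM, {bp_max} bp)"
    )
    return "\n".join(lines) + "\n"
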