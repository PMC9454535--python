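"""Variant prioritization cascade.

Candidate germline variants pass, in order, a read-depth filter, a variant
allele fraction (VAF) filter, a population-frequency filter and a gene-panel
restriction; survivors are then routed to manual classification if they are
already reported pathogenic (ClinVar/InterVar), are loss-of-function, or are
VUS with in-silico support (REVEL/M-CAP for missense, a splice-impact
verdict for splicing candidates).  Every input variant receives exactly one
:class:`Disposition`, so the audit trail partitions the input.

Boundary semantics (all configurable): keep depth >= 30 reads, VAF >= 25%,
population MAF <= 1%; in-silico thresholds are strict (REVEL > 0.7,
M-CAP > 0.025).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

from .io import (
    AnnotatedVariant,
    ClinSig,
    Consequence,
    GenePanel,
    SpliceVerdict,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: consequences counted as loss-of-function (nonsense, frameshift,
#: canonical splice-site disruption)
LOF_CONSEQUENCES = frozenset({
    Consequence.STOP_GAINED,
    Consequence.FRAMESHIFT_INDEL,
    Consequence.SPLICE_DONOR,
    Consequence.SPLICE_ACCEPTOR,
})

#: non-LoF consequences eligible for the splice-impact route
_SPLICE_ROUTE_CONSEQUENCES = frozenset({
    Consequence.MISSENSE,
    Consequence.SPLICE_REGION,
    Consequence.SYNONYMOUS,
    Consequence.OTHER,
})

_PATHOGENIC_ASSERTIONS = frozenset({ClinSig.PATHOGENIC, ClinSig.LIKELY_PATHOGENIC})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults are the documented study values."""

    min_depth: int = 30
    min_vaf: float = 0.25
    max_maf: float = 0.01
    revel_threshold: float = 0.7
    mcap_threshold: float = 0.025

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValidationError(f"min_depth must be >= 0, got {self.min_depth}")
        for name in ("min_vaf", "max_maf", "revel_threshold", "mcap_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} out of [0,1]: {value}")


class Outcome(str, enum.Enum):
    REMOVED = "removed"
    SELECTED = "selected"


class RemovalReason(str, enum.Enum):
    LOW_DEPTH = "low_depth"
    LOW_VAF = "low_vaf"
    COMMON = "common"
    OFF_PANEL = "off_panel"
    NO_ROUTE = "no_route"


class Route(str, enum.Enum):
    REPORTED_PATHOGENIC = "reported_pathogenic"
    LOF = "lof"
    INSILICO_MISSENSE = "insilico_missense"
    INSILICO_SPLICE = "insilico_splice"


@dataclass(frozen=True)
class Disposition:
    """Audit-trail outcome of the cascade for one variant."""

    variant: AnnotatedVariant
    outcome: Outcome
    reason: RemovalReason | None = None
    route: Route | None = None

    def __post_init__(self) -> None:
        if (self.outcome is Outcome.REMOVED) != (self.reason is not None):
            raise ValidationError("removed dispositions carry exactly a reason")
        if (self.outcome is Outcome.SELECTED) != (self.route is not None):
            raise ValidationError("selected dispositions carry exactly a route")


def passes_depth(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Keep variants covered by at least ``min_depth`` reads."""
    return v.depth >= cfg.min_depth


def passes_vaf(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Keep variants with VAF at or above ``min_vaf`` (germline support)."""
    return v.vaf >= cfg.min_vaf


def passes_popfreq(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Keep variants rare in every declared population database.

    A variant absent from all databases is treated as rare.
    """
    return all(af <= cfg.max_maf for af in v.pop_af.values())


def in_panel(v: AnnotatedVariant, panel: GenePanel) -> bool:
    return v.gene in panel


def is_lof(v: AnnotatedVariant) -> bool:
    """Nonsense, frameshift, or canonical splice-site disrupting variant."""
    return v.consequence in LOF_CONSEQUENCES


def is_reported_pathogenic(v: AnnotatedVariant) -> bool:
    """Pathogenic or likely pathogenic per ClinVar or InterVar.

    Conflicting ClinVar assertions do not count as reported pathogenic.
    """
    return v.clinvar in _PATHOGENIC_ASSERTIONS or v.intervar in _PATHOGENIC_ASSERTIONS


def insilico_route(v: AnnotatedVariant, cfg: FilterConfig) -> Route | None:
    """In-silico support route for VUS, or None.

    Missense variants qualify on REVEL/M-CAP above the (strict) thresholds;
    non-LoF variants with a splice-impact verdict qualify via the splice
    route.  Missing scores never satisfy a threshold.
    """
    if v.consequence is Consequence.MISSENSE and (
        (v.revel is not None and v.revel > cfg.revel_threshold)
        or (v.mcap is not None and v.mcap > cfg.mcap_threshold)
    ):
        return Route.INSILICO_MISSENSE
    if (
        v.splice_verdict is SpliceVerdict.IMPACT
        and v.consequence in _SPLICE_ROUTE_CONSEQUENCES
    ):
        return Route.INSILICO_SPLICE
    return None


def route_variant(v: AnnotatedVariant, cfg: FilterConfig) -> Route | None:
    """Route precedence: reported pathogenic > LoF > in-silico."""
    if is_reported_pathogenic(v):
        return Route.REPORTED_PATHOGENIC
    if is_lof(v):
        return Route.LOF
    return insilico_route(v, cfg)


def prioritize(
    variants: Sequence[AnnotatedVariant],
    panel: GenePanel,
    cfg: FilterConfig | None = None,
) -> list[Disposition]:
    """Run the full cascade; returns one Disposition per input variant.

    Removal reasons are assigned in the fixed order low_depth, low_vaf,
    common, off_panel; QC survivors with no classification route are
    removed as ``no_route``.
    """
    cfg = cfg or FilterConfig()
    dispositions: list[Disposition] = []
    for v in variants:
        if not passes_depth(v, cfg):
            reason = RemovalReason.LOW_DEPTH
        elif not passes_vaf(v, cfg):
            reason = RemovalReason.LOW_VAF
        elif not passes_popfreq(v, cfg):
            reason = RemovalReason.COMMON
        elif not in_panel(v, panel):
            reason = RemovalReason.OFF_PANEL
        else:
            route = route_variant(v, cfg)
            if route is None:
                reason = RemovalReason.NO_ROUTE
            else:
                dispositions.append(Disposition(v, Outcome.SELECTED, route=route))
                continue
        dispositions.append(Disposition(v, Outcome.REMOVED, reason=reason))

    n_sel = sum(d.outcome is Outcome.SELECTED for d in dispositions)
    logger.info(
        "prioritization funnel: %d in, %d selected, %d removed",
        len(variants), n_sel, len(variants) - n_sel,
    )
    return dispositions


def funnel_counts(dispositions: Sequence[Disposition]) -> dict[str, int]:
    """Per-reason/per-route counts of the cascade, for logging and manifests."""
    counts: dict[str, int] = {"input": len(dispositions)}
    for reason in RemovalReason:
        counts[f"removed_{reason.value}"] = sum(
            d.reason is reason for d in dispositions
        )
    for route in Route:
        counts[f"selected_{route.value}"] = sum(
            d.route is route for d in dispositions
        )
    counts["selected"] = sum(d.outcome is Outcome.SELECTED for d in dispositions)
    return counts
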