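"""ACMG/AMP evidence assignment and tier combination.

Only the evidence codes that are computable from the variant annotations are
assigned automatically (PVS1, PM2, PP3, BP4, BA1, BS1); everything that
needs literature, segregation or functional data is supplied as manually
curated codes from a curation TSV.  Codes are combined with the 2015
ACMG/AMP combining rules into the five tiers, reported both as names
(benign .. pathogenic) and as the Roman numerals I-V used in clinical
reports.  Evidence-strength modulation (e.g. downgraded PVS1) is out of
scope: each code carries its fixed guideline strength.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import AnnotatedVariant, SpliceVerdict, ValidationError
from .prioritization import Disposition, Route, is_lof

#: closed ACMG/AMP evidence-code vocabulary
ACMG_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)


class Provenance(str, enum.Enum):
    AUTO = "auto"
    MANUAL = "manual"


class Tier(str, enum.Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"


_TIER_TO_ROMAN = {
    Tier.BENIGN: "I",
    Tier.LIKELY_BENIGN: "II",
    Tier.VUS: "III",
    Tier.LIKELY_PATHOGENIC: "IV",
    Tier.PATHOGENIC: "V",
}
_ROMAN_TO_TIER = {r: t for t, r in _TIER_TO_ROMAN.items()}


@dataclass(frozen=True)
class AcmgClass:
    tier: Tier

    @property
    def roman(self) -> str:
        return _TIER_TO_ROMAN[self.tier]

    @classmethod
    def from_roman(cls, roman: str) -> "AcmgClass":
        return cls(_ROMAN_TO_TIER[roman])


def to_roman(c: AcmgClass | Tier) -> str:
    tier = c.tier if isinstance(c, AcmgClass) else c
    return _TIER_TO_ROMAN[tier]


@dataclass(frozen=True)
class EvidenceSet:
    """A set of ACMG codes with per-code provenance (auto vs manual)."""

    provenance: Mapping[str, Provenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.provenance) - ACMG_CODES
        if unknown:
            raise ValidationError(f"unknown ACMG codes: {sorted(unknown)}")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self.provenance)

    def merged_with(self, codes: Iterable[str], provenance: Provenance) -> "EvidenceSet":
        merged = dict(self.provenance)
        for code in codes:
            merged.setdefault(code, provenance)
        return EvidenceSet(merged)

    def __contains__(self, code: str) -> bool:
        return code in self.provenance


@dataclass(frozen=True)
class AcmgConfig:
    """Frequency bounds for the auto-assignable codes.

    ``pm2_max_af`` and ``bs1_max_af`` are configuration defaults of this
    pipeline; the BA1 stand-alone bound (5%) is the guideline value.
    """

    pm2_max_af: float = 1e-4
    bs1_max_af: float = 0.01
    ba1_min_af: float = 0.05
    revel_threshold: float = 0.7
    mcap_threshold: float = 0.025

    def __post_init__(self) -> None:
        for name in ("pm2_max_af", "bs1_max_af", "ba1_min_af",
                     "revel_threshold", "mcap_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} out of [0,1]: {value}")


def assign_auto_evidence(
    v: AnnotatedVariant,
    lof_mechanism_genes: Iterable[str] = (),
    cfg: AcmgConfig | None = None,
) -> EvidenceSet:
    """Assign the automatable evidence codes for one variant.

    - PVS1: LoF variant in a gene where LoF is a known disease mechanism
      (``lof_mechanism_genes``, case-normalized).
    - PM2: absent from, or below ``pm2_max_af`` in, every declared
      population database.
    - PP3: in-silico support (REVEL/M-CAP above threshold, or a
      splice-impact verdict).
    - BP4: every present score at or below its threshold and an explicit
      no-impact splice verdict.
    - BA1 / BS1: population frequency at/above the stand-alone (5%) or
      disease-implausible bound.
    """
    cfg = cfg or AcmgConfig()
    mech = {g.upper() for g in lof_mechanism_genes}
    codes: set[str] = set()

    if is_lof(v) and v.gene.upper() in mech:
        codes.add("PVS1")
    if all(af < cfg.pm2_max_af for af in v.pop_af.values()):
        codes.add("PM2")
    high_score = (
        (v.revel is not None and v.revel > cfg.revel_threshold)
        or (v.mcap is not None and v.mcap > cfg.mcap_threshold)
    )
    if high_score or v.splice_verdict is SpliceVerdict.IMPACT:
        codes.add("PP3")
    if not high_score and v.splice_verdict is SpliceVerdict.NO_IMPACT:
        codes.add("BP4")
    if any(af >= cfg.ba1_min_af for af in v.pop_af.values()):
        codes.add("BA1")
    if any(af > cfg.bs1_max_af for af in v.pop_af.values()):
        codes.add("BS1")
    return EvidenceSet({c: Provenance.AUTO for c in codes})


def combine_evidence(e: EvidenceSet) -> AcmgClass:
    """Combine ACMG codes into a tier per the 2015 combining rules.

    Satisfying both a pathogenic-side and a benign-side rule, or neither,
    yields VUS; BA1 alone is stand-alone benign.
    """
    codes = e.codes
    pvs = "PVS1" in codes
    ps = sum(c.startswith("PS") for c in codes)
    pm = sum(c.startswith("PM") for c in codes)
    pp = sum(c.startswith("PP") for c in codes)
    ba = "BA1" in codes
    bs = sum(c.startswith("BS") for c in codes)
    bp = sum(c.startswith("BP") for c in codes)

    pathogenic = (
        (pvs and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs and pm >= 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return AcmgClass(Tier.VUS)
    if pathogenic:
        return AcmgClass(Tier.PATHOGENIC)
    if likely_pathogenic:
        return AcmgClass(Tier.LIKELY_PATHOGENIC)
    if benign:
        return AcmgClass(Tier.BENIGN)
    if likely_benign:
        return AcmgClass(Tier.LIKELY_BENIGN)
    return AcmgClass(Tier.VUS)


@dataclass(frozen=True)
class ClassifiedVariant:
    """A selected variant together with its route, evidence and tier."""

    variant: AnnotatedVariant
    route: Route
    evidence: EvidenceSet
    acmg: AcmgClass


def read_curation(path: str | Path) -> dict[str, dict[str, Provenance]]:
    """Read a curation TSV (patient, variant_key, code, provenance).

    ``variant_key`` is ``chrom:pos:ref:alt``; returns per-call code maps
    keyed by ``patient:chrom:pos:ref:alt``.
    """
    curated: dict[str, dict[str, Provenance]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"patient", "variant_key", "code", "provenance"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValidationError(f"{path}: curation TSV needs columns {sorted(required)}")
        for row in reader:
            code = row["code"].strip().upper()
            if code not in ACMG_CODES:
                raise ValidationError(f"{path}: unknown ACMG code {code!r}")
            key = f"{row['patient']}:{row['variant_key']}"
            curated.setdefault(key, {})[code] = Provenance(row["provenance"])
    return curated


def write_curation(
    curated: Mapping[str, Mapping[str, Provenance]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["patient", "variant_key", "code", "provenance"])
        for key in sorted(curated):
            patient, variant_key = key.split(":", 1)
            for code in sorted(curated[key]):
                w.writerow([patient, variant_key, code, curated[key][code].value])


def classify_selected(
    dispositions: Sequence[Disposition],
    lof_mechanism_genes: Iterable[str] = (),
    curation: Mapping[str, Mapping[str, Provenance]] | None = None,
    cfg: AcmgConfig | None = None,
) -> list[ClassifiedVariant]:
    """Classify every selected variant: auto evidence + curated codes."""
    curation = curation or {}
    mech = list(lof_mechanism_genes)
    out: list[ClassifiedVariant] = []
    for d in dispositions:
        if d.route is None:
            continue
        ev = assign_auto_evidence(d.variant, mech, cfg)
        manual = curation.get(d.variant.key, {})
        ev = EvidenceSet({**dict(ev.provenance), **manual})
        out.append(ClassifiedVariant(d.variant, d.route, ev, combine_evidence(ev)))
    return out
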