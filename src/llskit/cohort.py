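"""Patient triage, cohort summaries and group-comparison statistics.

Triage reproduces the clinical eligibility flow for mismatch-repair (MMR)
deficient tumors: tumors losing PMS2/MSH2/MSH6 expression (without MLH1)
go straight to germline testing; MLH1-deficient tumors are gated on BRAF
p.(Val600Glu) status — wild-type proceeds to germline testing regardless of
MLH1 promoter methylation, mutant suggests sporadic origin and is not
tested.  Summaries compute the per-class variant shares and the carrier
rate (a carrier harbors at least one class IV/V variant); group comparisons
use ANOVA for ages, Kruskal-Wallis for tumor counts, and chi-square or
Fisher's exact test for 2x2 tables of carrier status versus tumor features.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .acmg import ClassifiedVariant, Tier
from .io import LlskitError, ValidationError

logger = logging.getLogger(__name__)

CARRIER_TIERS = frozenset({Tier.LIKELY_PATHOGENIC, Tier.PATHOGENIC})

MMR_PROTEINS = frozenset({"MLH1", "PMS2", "MSH2", "MSH6"})


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class MsiStatus(str, enum.Enum):
    MSI = "MSI"
    MSS = "MSS"
    UNKNOWN = "unknown"


class BrafStatus(str, enum.Enum):
    WILDTYPE = "wildtype"
    MUTANT = "mutant"
    INCONCLUSIVE = "inconclusive"
    UNTESTED = "untested"


class Methylation(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class ClinicalCriteria(str, enum.Enum):
    AMSTERDAM = "amsterdam"
    BETHESDA = "bethesda"
    REVISED_BETHESDA = "revised_bethesda"


class TriageDecision(str, enum.Enum):
    GERMLINE_TEST = "germline_test"
    NO_TEST = "no_test"
    EXCLUDED = "excluded"
    NEEDS_BRAF = "needs_braf"


@dataclass(frozen=True)
class Patient:
    """Phenotype record: tumors, IHC loss pattern, MSI/BRAF/methylation."""

    id: str
    sex: Sex
    tumors: tuple[tuple[str, float], ...]  # (site, age at diagnosis)
    ihc_loss: frozenset[str] = frozenset()
    msi: MsiStatus = MsiStatus.UNKNOWN
    mlh1_methylated: Methylation = Methylation.UNKNOWN
    braf_v600e: BrafStatus = BrafStatus.UNTESTED
    criteria: ClinicalCriteria = ClinicalCriteria.BETHESDA
    family_tumor_count: int = 0
    family_ls_tumors: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.ihc_loss) - MMR_PROTEINS
        if unknown:
            raise ValidationError(f"unknown MMR proteins in ihc_loss: {sorted(unknown)}")
        if any(age < 0 for _, age in self.tumors):
            raise ValidationError(f"negative diagnosis age for patient {self.id}")

    @property
    def first_tumor(self) -> tuple[str, float] | None:
        return min(self.tumors, key=lambda t: t[1]) if self.tumors else None


def triage(p: Patient) -> TriageDecision:
    """Eligibility decision for germline testing of one patient.

    MLH1-deficient tumors require a conclusive-or-inconclusive BRAF V600E
    result: wild-type (and inconclusive, which does not demonstrate the
    sporadic-origin mutation) proceeds to testing regardless of MLH1
    methylation; mutant is not tested; an untested BRAF yields the explicit
    ``NEEDS_BRAF`` status rather than a silent decision.  Tumors without
    IHC loss are eligible only when MSI-positive.
    """
    if not p.ihc_loss:
        return (
            TriageDecision.GERMLINE_TEST
            if p.msi is MsiStatus.MSI
            else TriageDecision.EXCLUDED
        )
    if "MLH1" in p.ihc_loss:
        if p.braf_v600e in (BrafStatus.WILDTYPE, BrafStatus.INCONCLUSIVE):
            return TriageDecision.GERMLINE_TEST
        if p.braf_v600e is BrafStatus.MUTANT:
            return TriageDecision.NO_TEST
        return TriageDecision.NEEDS_BRAF
    # isolated PMS2 / MSH2 / MSH6 loss: no BRAF gate
    return TriageDecision.GERMLINE_TEST


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def percent_round(numerator: float, denominator: float) -> float:
    """Percentage with one decimal, half-up (e.g. 107/319 -> 33.5)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def class_shares(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-class percentage shares of classified variants (one decimal)."""
    total = sum(counts.values())
    return {name: percent_round(n, total) for name, n in counts.items()}


@dataclass(frozen=True)
class CohortResult:
    """Per-patient retained variants plus cohort-level summaries."""

    patients: tuple[Patient, ...]
    classified: tuple[ClassifiedVariant, ...]
    class_counts: Mapping[str, int]
    class_share_pct: Mapping[str, float]
    carriers: Mapping[str, bool]
    carrier_rate_pct: float
    first_tumor_sites: Mapping[str, int]
    age_mean: float
    age_sd: float

    @property
    def n_carriers(self) -> int:
        return sum(self.carriers.values())


def summarize_cohort(
    patients: Sequence[Patient], classified: Sequence[ClassifiedVariant]
) -> CohortResult:
    """Cohort summary: class shares, carrier rate, sites, age mean/SD."""
    ids = {p.id for p in patients}
    for cv in classified:
        if cv.variant.patient_id not in ids:
            raise LlskitError(
                f"classified variant for unknown patient {cv.variant.patient_id!r}"
            )

    class_counts = {t.value: 0 for t in Tier}
    for cv in classified:
        class_counts[cv.acmg.tier.value] += 1

    carriers = {p.id: False for p in patients}
    for cv in classified:
        if cv.acmg.tier in CARRIER_TIERS:
            carriers[cv.variant.patient_id] = True

    sites: dict[str, int] = {}
    ages: list[float] = []
    for p in patients:
        first = p.first_tumor
        if first is not None:
            sites[first[0]] = sites.get(first[0], 0) + 1
            ages.append(first[1])

    return CohortResult(
        patients=tuple(patients),
        classified=tuple(classified),
        class_counts=class_counts,
        class_share_pct=class_shares(class_counts),
        carriers=carriers,
        carrier_rate_pct=percent_round(sum(carriers.values()), len(patients))
        if patients else 0.0,
        first_tumor_sites=sites,
        age_mean=float(np.mean(ages)) if ages else float("nan"),
        age_sd=float(np.std(ages, ddof=1)) if len(ages) > 1 else float("nan"),
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d): rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def expected(self) -> np.ndarray:
        arr = self.to_array()
        return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the probability-mass method.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (with a
    small relative tolerance for ties).  Degenerate (zero-margin) tables
    return p = 1 with a warning.
    """
    arr = t.to_array()
    if t.total == 0 or 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        warnings.warn("degenerate 2x2 table (zero margin): p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def chi2_2x2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (df = 1) on a 2x2 table; no continuity correction
    by default.  Zero expected counts are an error (use Fisher instead)."""
    if np.any(t.expected() == 0):
        raise ValidationError(
            "chi-square undefined with zero expected counts; use fisher_exact_2x2"
        )
    res = stats.chi2_contingency(t.to_array(), correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def select_2x2_test(t: ContingencyTable2x2) -> str:
    """Pipeline policy: Fisher when any expected count < 5, else chi-square."""
    if t.total == 0 or np.any(t.expected() < 5):
        return "fisher"
    return "chi2"


def compare_2x2(t: ContingencyTable2x2) -> dict:
    test = select_2x2_test(t)
    if test == "fisher":
        return {"test": "fisher", "p": fisher_exact_2x2(t)}
    statistic, p = chi2_2x2(t)
    return {"test": "chi2", "statistic": statistic, "p": p}


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within decomposition).

    Zero within-group variance with equal group means yields F = 0, p = 1.
    For two groups, F equals the squared pooled two-sample t statistic.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("ANOVA needs >= 2 nonempty groups")
    n_total = sum(len(g) for g in groups)
    if n_total <= len(groups):
        raise ValidationError("ANOVA needs total n > number of groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    f, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(f):  # zero within-group variance, unequal means
        return float("inf"), 0.0
    return f, p


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction (chi-square p)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("Kruskal-Wallis needs >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Phenotype table I/O
# ---------------------------------------------------------------------------

_PHENO_COLUMNS = [
    "patient_id", "sex", "tumors", "ihc_loss", "msi", "mlh1_methylated",
    "braf_v600e", "criteria", "family_tumor_count", "family_ls_tumors",
]


def write_phenotypes(patients: Sequence[Patient], path) -> None:
    """Write the phenotype TSV (tumors serialized as site@age;site@age)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PHENO_COLUMNS)
        for p in sorted(patients, key=lambda p: p.id):
            w.writerow([
                p.id, p.sex.value,
                ";".join(f"{site}@{age:g}" for site, age in p.tumors),
                ";".join(sorted(p.ihc_loss)), p.msi.value,
                p.mlh1_methylated.value, p.braf_v600e.value, p.criteria.value,
                p.family_tumor_count, "yes" if p.family_ls_tumors else "no",
            ])


def read_phenotypes(path) -> list[Patient]:
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(_PHENO_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(f"{path}: missing phenotype TSV columns")
        out = []
        for row in reader:
            tumors = tuple(
                (site, float(age))
                for site, age in (t.split("@") for t in row["tumors"].split(";") if t)
            )
            out.append(Patient(
                id=row["patient_id"], sex=Sex(row["sex"]), tumors=tumors,
                ihc_loss=frozenset(x for x in row["ihc_loss"].split(";") if x),
                msi=MsiStatus(row["msi"]),
                mlh1_methylated=Methylation(row["mlh1_methylated"]),
                braf_v600e=BrafStatus(row["braf_v600e"]),
                criteria=ClinicalCriteria(row["criteria"]),
                family_tumor_count=int(row["family_tumor_count"]),
                family_ls_tumors=row["family_ls_tumors"] == "yes",
            ))
    return out


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_report(result: CohortResult, path) -> None:
    """Write the final TSV report: one row per retained variant, then a
    per-patient summary block; deterministic row order."""
    from .io import _chrom_sort_key  # stable ordering shared with io

    rows = sorted(
        result.classified,
        key=lambda cv: (
            cv.variant.patient_id, _chrom_sort_key(cv.variant.chrom),
            cv.variant.pos, cv.variant.alt,
        ),
    )
    with open(path, "w", newline="") as fh:
        fh.write(
            "patient\tgene\ttranscript\thgvs_c\thgvs_p\troute\t"
            "acmg_codes\tacmg_class\tacmg_roman\tmanual_review\n"
        )
        for cv in rows:
            v = cv.variant
            fh.write("\t".join([
                v.patient_id, v.gene, v.transcript, v.hgvs_c, v.hgvs_p,
                cv.route.value, ",".join(sorted(cv.evidence.codes)),
                cv.acmg.tier.value, cv.acmg.roman,
                "yes" if v.manual_review else "no",
            ]) + "\n")
        fh.write("\n## per-patient summary\n")
        fh.write("patient\tn_retained\tn_class_iv_v\tcarrier\n")
        per_patient: dict[str, list[ClassifiedVariant]] = {p.id: [] for p in result.patients}
        for cv in rows:
            per_patient.setdefault(cv.variant.patient_id, []).append(cv)
        for pid in sorted(per_patient):
            cvs = per_patient[pid]
            n_iv_v = sum(cv.acmg.tier in CARRIER_TIERS for cv in cvs)
            fh.write(f"{pid}\t{len(cvs)}\t{n_iv_v}\t{'yes' if n_iv_v else 'no'}\n")
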