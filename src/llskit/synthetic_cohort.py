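"""Seeded synthetic Lynch-like syndrome cohorts with planted truth labels.

The generator emulates the structure of a 20-patient Lynch-like syndrome
(LLS) cohort: ages at first diagnosis ~ Normal(48.2, 7.7) truncated at 18,
first-tumor sites drawn as colorectal 75% / endometrium 10% / ovary 10% /
stomach 5%, 60% female, and a 35% carrier fraction.  Mismatch-repair IHC
loss patterns follow the typical clinical mix (half the cohort
MLH1/PMS2-deficient, 60% of those MLH1-promoter methylated, BRAF V600E
wild-type except one inconclusive case; the rest split across
MSH2/MSH6-type losses and one MSI-positive tumor without IHC loss).

Each patient receives a pool of planted variants, one truth category per
variant, chosen so every branch of the prioritization cascade is exercised:
removable categories (common, low_depth, low_vaf, off_panel, plain_vus) and
retainable ones (lof_rare, reported_pathogenic, high_score_missense,
splice_impact).  Carrier patients receive at least one variant whose
automatic ACMG evidence reaches class IV/V.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .acmg import Provenance
from .cohort import (
    BrafStatus,
    ClinicalCriteria,
    Methylation,
    MsiStatus,
    Patient,
    Sex,
    write_phenotypes,
)
from .io import (
    AnnotatedVariant,
    ClinSig,
    Consequence,
    GenePanel,
    LlskitError,
    SpliceVerdict,
    ValidationError,
    Zygosity,
    write_annotated_vcf,
    write_gene_panel,
)
from .prioritization import Disposition, Outcome

_BASES = "ACGT"


class TruthCategory(str, enum.Enum):
    COMMON = "common"
    LOW_DEPTH = "low_depth"
    LOW_VAF = "low_vaf"
    OFF_PANEL = "off_panel"
    LOF_RARE = "lof_rare"
    REPORTED_PATHOGENIC = "reported_pathogenic"
    HIGH_SCORE_MISSENSE = "high_score_missense"
    SPLICE_IMPACT = "splice_impact"
    PLAIN_VUS = "plain_vus"


#: categories the cascade must keep / must drop
RETAINABLE = frozenset({
    TruthCategory.LOF_RARE,
    TruthCategory.REPORTED_PATHOGENIC,
    TruthCategory.HIGH_SCORE_MISSENSE,
    TruthCategory.SPLICE_IMPACT,
})
REMOVABLE = frozenset(TruthCategory) - RETAINABLE


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 20
    age_mean: float = 48.2
    age_sd: float = 7.7
    min_age: float = 18.0
    site_probs: Mapping[str, float] = field(default_factory=lambda: {
        "colorectal": 0.75, "endometrium": 0.10, "ovary": 0.10, "stomach": 0.05,
    })
    female_fraction: float = 0.60
    carrier_fraction: float = 0.35
    #: per-patient counts of planted non-carrier categories
    category_counts: Mapping[str, int] = field(default_factory=lambda: {
        "common": 3, "low_depth": 2, "low_vaf": 2, "off_panel": 2,
        "plain_vus": 3, "high_score_missense": 1, "splice_impact": 1,
    })
    panel_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if abs(sum(self.site_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("site probabilities must sum to 1")
        if any(p < 0 for p in self.site_probs.values()):
            raise ValidationError("site probabilities must be nonnegative")
        for name in ("female_fraction", "carrier_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} out of [0,1]")
        if any(c < 0 for c in self.category_counts.values()):
            raise ValidationError("category counts must be >= 0")
        unknown = set(self.category_counts) - {c.value for c in TruthCategory}
        if unknown:
            raise ValidationError(f"unknown truth categories: {sorted(unknown)}")
        if self.age_sd <= 0 or self.panel_size < 1:
            raise ValidationError("age_sd and panel_size must be positive")


@dataclass(frozen=True)
class SyntheticCohort:
    patients: tuple[Patient, ...]
    variants: Mapping[str, tuple[AnnotatedVariant, ...]]  # patient -> pool
    panel: GenePanel
    truth: Mapping[str, TruthCategory]  # variant.key -> category
    lof_mechanism_genes: frozenset[str]
    carrier_ids: frozenset[str]

    def all_variants(self) -> list[AnnotatedVariant]:
        return [v for pid in sorted(self.variants) for v in self.variants[pid]]


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------

def _draw_age(rng: np.random.Generator, cfg: SimConfig) -> float:
    while True:
        age = rng.normal(cfg.age_mean, cfg.age_sd)
        if age >= cfg.min_age:
            return round(float(age), 1)


def _ihc_patterns(n: int) -> list[tuple[frozenset[str], Methylation, BrafStatus, MsiStatus]]:
    """Clinical IHC/methylation/BRAF mix, scaled from the 20-patient layout."""
    patterns = []
    n_mlh1 = n // 2
    n_meth = round(0.6 * n_mlh1)
    for i in range(n_mlh1):
        methylated = i < n_meth
        braf = BrafStatus.INCONCLUSIVE if (methylated and i == 0 and n_meth > 1) else BrafStatus.WILDTYPE
        patterns.append((
            frozenset({"MLH1", "PMS2"}),
            Methylation.YES if methylated else Methylation.NO,
            braf, MsiStatus.MSI,
        ))
    rest = n - n_mlh1
    rest_patterns = [
        (frozenset({"MSH2", "MSH6"}), Methylation.NO, BrafStatus.UNTESTED, MsiStatus.MSI),
        (frozenset({"MSH6"}), Methylation.NO, BrafStatus.UNTESTED, MsiStatus.MSI),
        (frozenset({"PMS2"}), Methylation.NO, BrafStatus.UNTESTED, MsiStatus.MSI),
        (frozenset(), Methylation.YES, BrafStatus.UNTESTED, MsiStatus.MSI),
    ]
    for i in range(rest):
        patterns.append(rest_patterns[i % len(rest_patterns)])
    return patterns


def _criteria_mix(n: int) -> list[ClinicalCriteria]:
    # 25% Amsterdam / 40% Bethesda / 35% revised Bethesda
    n_ams = round(0.25 * n)
    n_bet = round(0.40 * n)
    out = [ClinicalCriteria.AMSTERDAM] * n_ams + [ClinicalCriteria.BETHESDA] * n_bet
    out += [ClinicalCriteria.REVISED_BETHESDA] * (n - len(out))
    return out[:n]


def _generate_patients(rng: np.random.Generator, cfg: SimConfig) -> list[Patient]:
    n = cfg.n_patients
    sites = list(rng.choice(
        list(cfg.site_probs), size=n, p=list(cfg.site_probs.values())
    ))
    # gynecologic first tumors force female; fill the remaining quota randomly
    n_female = round(cfg.female_fraction * n)
    sexes: list[Sex | None] = [
        Sex.FEMALE if s in ("endometrium", "ovary") else None for s in sites
    ]
    open_idx = [i for i, s in enumerate(sexes) if s is None]
    n_more = max(0, n_female - sum(s is Sex.FEMALE for s in sexes))
    for i in rng.permutation(open_idx)[:n_more]:
        sexes[i] = Sex.FEMALE
    sexes = [s or Sex.MALE for s in sexes]

    ihc = _ihc_patterns(n)
    criteria = _criteria_mix(n)
    order = rng.permutation(n)  # decouple IHC/criteria layout from patient index
    second_sites = ["colorectal", "endometrium", "breast", "non_melanoma_skin"]

    patients = []
    for i in range(n):
        age = _draw_age(rng, cfg)
        tumors = [(str(sites[i]), age)]
        if rng.random() < 0.25:  # ~5/20 second tumors
            site2 = second_sites[int(rng.integers(len(second_sites)))]
            if sexes[i] is Sex.MALE and site2 == "endometrium":
                site2 = "colorectal"
            tumors.append((site2, round(age + max(1.0, float(rng.normal(11.0, 4.0))), 1)))
        loss, meth, braf, msi = ihc[order[i]]
        crit = criteria[order[i]]
        patients.append(Patient(
            id=f"P{i + 1:03d}",
            sex=sexes[i],
            tumors=tuple(tumors),
            ihc_loss=loss,
            msi=msi,
            mlh1_methylated=meth,
            braf_v600e=braf,
            criteria=crit,
            family_tumor_count=int(rng.poisson(5)),
            family_ls_tumors=bool(rng.random() < 0.75) or crit is ClinicalCriteria.AMSTERDAM,
        ))
    return patients


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[int(rng.integers(4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(4))]
    return ref, alt


def _rare_af(rng: np.random.Generator) -> dict[str, float]:
    # absent from both databases half the time; otherwise well below 1e-4
    if rng.random() < 0.5:
        return {}
    return {"gnomad": round(float(rng.uniform(1e-6, 9e-5)), 8)}


def _plant_variant(
    rng: np.random.Generator,
    pid: str,
    category: TruthCategory,
    panel_genes: Sequence[str],
    used_positions: set[tuple[str, int]],
) -> AnnotatedVariant:
    chrom = str(int(rng.integers(1, 23)))
    pos = int(rng.integers(10_000, 50_000_000))
    while (chrom, pos) in used_positions:
        pos = int(rng.integers(10_000, 50_000_000))
    used_positions.add((chrom, pos))

    gene = str(panel_genes[int(rng.integers(len(panel_genes)))])
    ref, alt = _snv_alleles(rng)
    depth = int(rng.integers(60, 220))
    vaf = round(float(np.clip(rng.normal(0.5, 0.04), 0.30, 0.70)), 4)
    consequence = Consequence.MISSENSE
    pop_af: dict[str, float] = _rare_af(rng)
    clinvar = ClinSig.ABSENT
    revel: float | None = None
    mcap: float | None = None
    splice = SpliceVerdict.ABSENT
    hgvs_c = f"c.{int(rng.integers(1, 3000))}{ref}>{alt}"

    if category is TruthCategory.COMMON:
        pop_af = {"gnomad": round(float(rng.uniform(0.02, 0.30)), 6)}
        if rng.random() < 0.5:
            pop_af["abraom"] = round(float(rng.uniform(0.02, 0.30)), 6)
    elif category is TruthCategory.LOW_DEPTH:
        depth = int(rng.integers(1, 30))
    elif category is TruthCategory.LOW_VAF:
        vaf = round(float(rng.uniform(0.03, 0.24)), 4)
    elif category is TruthCategory.OFF_PANEL:
        gene = f"OFFP{int(rng.integers(1000)):04d}"
        revel = round(float(rng.uniform(0.75, 0.99)), 4)
    elif category is TruthCategory.LOF_RARE:
        consequence = Consequence(str(rng.choice([
            Consequence.STOP_GAINED.value,
            Consequence.FRAMESHIFT_INDEL.value,
            Consequence.SPLICE_DONOR.value,
            Consequence.SPLICE_ACCEPTOR.value,
        ])))
        if consequence is Consequence.FRAMESHIFT_INDEL:
            ndel = int(rng.integers(1, 4))
            ref = ref + "".join(_BASES[int(rng.integers(4))] for _ in range(ndel))
            alt = ref[0]
            start = int(rng.integers(1, 3000))
            hgvs_c = f"c.{start}del" if ndel == 1 else f"c.{start}_{start + ndel - 1}del"
        elif consequence in (Consequence.SPLICE_DONOR, Consequence.SPLICE_ACCEPTOR):
            splice = SpliceVerdict.IMPACT
            off = "+1" if consequence is Consequence.SPLICE_DONOR else "-2"
            hgvs_c = f"c.{int(rng.integers(1, 3000))}{off}{ref}>{alt}"
    elif category is TruthCategory.REPORTED_PATHOGENIC:
        # reported in ClinVar/InterVar and LoF, so automatic evidence alone
        # reaches class IV/V for planted carriers
        consequence = Consequence.STOP_GAINED
        clinvar = ClinSig.PATHOGENIC if rng.random() < 0.7 else ClinSig.LIKELY_PATHOGENIC
    elif category is TruthCategory.HIGH_SCORE_MISSENSE:
        revel = round(float(rng.uniform(0.75, 0.99)), 4)
        if rng.random() < 0.5:
            mcap = round(float(rng.uniform(0.03, 0.4)), 4)
    elif category is TruthCategory.SPLICE_IMPACT:
        consequence = Consequence(
            str(rng.choice([Consequence.SYNONYMOUS.value, Consequence.SPLICE_REGION.value]))
        )
        splice = SpliceVerdict.IMPACT
    elif category is TruthCategory.PLAIN_VUS:
        revel = round(float(rng.uniform(0.0, 0.6)), 4)
        splice = SpliceVerdict.NO_IMPACT

    return AnnotatedVariant(
        patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        transcript=f"NM_{int(rng.integers(100000, 999999))}.1",
        hgvs_c=hgvs_c,
        consequence=consequence, depth=depth, vaf=vaf, pop_af=pop_af,
        clinvar=clinvar, revel=revel, mcap=mcap, splice_verdict=splice,
        zygosity=Zygosity.HET,
    )


def generate_cohort(cfg: SimConfig | None = None) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort with truth labels."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    panel_genes = [f"GENE{i:04d}" for i in range(cfg.panel_size)]
    panel = GenePanel(symbols=frozenset(panel_genes))
    patients = _generate_patients(rng, cfg)

    n_carriers = round(cfg.carrier_fraction * cfg.n_patients)
    carrier_ids = {
        patients[i].id
        for i in rng.choice(cfg.n_patients, size=n_carriers, replace=False)
    }

    variants: dict[str, tuple[AnnotatedVariant, ...]] = {}
    truth: dict[str, TruthCategory] = {}
    used_positions: set[tuple[str, int]] = set()
    carrier_rank = 0
    for p in patients:
        pool: list[AnnotatedVariant] = []
        for name, count in cfg.category_counts.items():
            category = TruthCategory(name)
            for _ in range(count):
                pool.append(_plant_variant(rng, p.id, category, panel_genes, used_positions))
                truth[pool[-1].key] = category
        if p.id in carrier_ids:
            # alternate the two class-IV/V-capable categories across carriers
            category = (
                TruthCategory.REPORTED_PATHOGENIC
                if carrier_rank % 2 == 0
                else TruthCategory.LOF_RARE
            )
            carrier_rank += 1
            pool.append(_plant_variant(rng, p.id, category, panel_genes, used_positions))
            truth[pool[-1].key] = category
        variants[p.id] = tuple(pool)

    return SyntheticCohort(
        patients=tuple(patients),
        variants=variants,
        panel=panel,
        truth=truth,
        # in synthetic cohorts LoF is a valid disease mechanism panel-wide
        lof_mechanism_genes=frozenset(panel_genes),
        carrier_ids=frozenset(carrier_ids),
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write per-patient VCFs, phenotype TSV, panel, LoF-gene list, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid in sorted(cohort.variants):
        write_annotated_vcf(cohort.variants[pid], outdir / f"{pid}.vcf")
    write_phenotypes(cohort.patients, outdir / "phenotypes.tsv")
    write_gene_panel(cohort.panel, outdir / "panel.txt")
    with open(outdir / "lof_mechanism_genes.txt", "w") as fh:
        for g in sorted(cohort.lof_mechanism_genes):
            fh.write(g + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("variant_key\tcategory\n")
        for key in sorted(cohort.truth):
            fh.write(f"{key}\t{cohort.truth[key].value}\n")


def read_truth(path: str | Path) -> dict[str, TruthCategory]:
    truth = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("variant_key"):
            raise ValidationError(f"{path}: not a truth TSV")
        for line in fh:
            key, category = line.rstrip("\n").split("\t")
            truth[key] = TruthCategory(category)
    return truth


# ---------------------------------------------------------------------------
# Recovery report
# ---------------------------------------------------------------------------

def planted_recovery_report(
    truth: Mapping[str, TruthCategory], dispositions: Sequence[Disposition]
) -> dict:
    """Confusion counts of cascade decisions against planted categories.

    Returns per-category n/selected counts plus the recall of retainable
    categories and the rejection rate of removable ones.
    """
    keys = {d.variant.key for d in dispositions}
    if keys != set(truth):
        missing = sorted(set(truth) ^ keys)[:5]
        raise LlskitError(f"truth/disposition key mismatch, e.g. {missing}")
    per_category = {
        c.value: {"n": 0, "selected": 0, "removed": 0} for c in TruthCategory
    }
    for d in dispositions:
        row = per_category[truth[d.variant.key].value]
        row["n"] += 1
        row["selected" if d.outcome is Outcome.SELECTED else "removed"] += 1

    def _rate(categories: frozenset[TruthCategory], field: str) -> float:
        n = sum(per_category[c.value]["n"] for c in categories)
        hit = sum(per_category[c.value][field] for c in categories)
        return hit / n if n else float("nan")

    return {
        "per_category": per_category,
        "retainable_recall": _rate(RETAINABLE, "selected"),
        "removable_rejection": _rate(REMOVABLE, "removed"),
    }


# ---------------------------------------------------------------------------
# Printed-table fixture: the eight class IV/V variants of the study cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table2Fixture:
    """The eight published class IV/V variants across seven patients.

    HGVS strings, REVEL scores, gnomAD frequencies, tumor sites/ages and
    printed classes are the published values; genomic coordinates,
    consequences, splice verdicts and the manual ACMG curation codes are
    reconstructions (synthetic stand-ins marked as such) chosen to be
    consistent with the published per-variant descriptions.
    """

    variants: tuple[AnnotatedVariant, ...]
    patients: tuple[Patient, ...]
    panel: GenePanel
    lof_mechanism_genes: frozenset[str]
    manual_codes: Mapping[str, Mapping[str, Provenance]]  # variant.key -> codes
    expected_roman: Mapping[str, str]  # variant.key -> printed class


def _t2_variant(pid, chrom, pos, ref, alt, gene, transcript, hgvs_c, hgvs_p,
                consequence, pop_af, clinvar=ClinSig.ABSENT, revel=None,
                splice=SpliceVerdict.ABSENT, depth=150, vaf=0.48):
    return AnnotatedVariant(
        patient_id=pid, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        transcript=transcript, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
        consequence=consequence, depth=depth, vaf=vaf, pop_af=pop_af,
        clinvar=clinvar, revel=revel, splice_verdict=splice,
        zygosity=Zygosity.HET,
    )


def table2_fixture() -> Table2Fixture:
    """Build the published eight-variant fixture set (7 patients).

    Genomic coordinates are synthetic placeholders; all annotation values
    that drive the cascade and the classification are the published ones.
    """
    M = Provenance.MANUAL
    v = [
        _t2_variant("1194", "3", 12_450_605, "C", "A", "PPARG", "NM_015869.5",
                    "c.1230C>A", "p.(Ser410Arg)", Consequence.MISSENSE,
                    {"gnomad": 1.60e-5}, revel=0.767),
        _t2_variant("142", "1", 45_797_228, "G", "A", "MUTYH", "NM_001128425.2",
                    "c.1187G>A", "p.(Gly396Asp)", Consequence.MISSENSE,
                    {"gnomad": 3.00e-3}, clinvar=ClinSig.PATHOGENIC, revel=0.954),
        _t2_variant("1728", "4", 2_094_236, "A", "G", "POLN", "NM_181808.2",
                    "c.1375-2A>G", "", Consequence.SPLICE_ACCEPTOR,
                    {"gnomad": 4.07e-6}, splice=SpliceVerdict.IMPACT),
        _t2_variant("313", "17", 8_237_439, "C", "T", "CTC1", "NM_025099.6",
                    "c.19C>T", "p.(Gln7Ter)", Consequence.STOP_GAINED,
                    {"gnomad": 1.68e-5}),
        _t2_variant("573", "4", 113_294_756, "TAACT", "T", "ALPK1", "NM_001102406.2",
                    "c.3428_3431del", "p.(Asn1143ThrfsTer5)",
                    Consequence.FRAMESHIFT_INDEL, {}),
        _t2_variant("635", "18", 49_866_859, "G", "A", "DCC", "NM_005215.4",
                    "c.1861G>A", "p.(Val621Met)", Consequence.MISSENSE,
                    {"gnomad": 2.00e-4}, revel=0.303, splice=SpliceVerdict.IMPACT),
        _t2_variant("837", "11", 108_121_787, "G", "A", "ATM", "NM_000051.3",
                    "c.3993+1G>A", "", Consequence.SPLICE_DONOR,
                    {"gnomad": 1.60e-5}, splice=SpliceVerdict.IMPACT),
        _t2_variant("837", "8", 53_023_312, "CA", "C", "ST18", "NM_014682.2",
                    "c.2093del", "p.(Lys698SerfsTer24)",
                    Consequence.FRAMESHIFT_INDEL, {}),
    ]
    by_gene = {x.gene: x for x in v}
    manual_codes = {
        # reconstructed curation: the published study reports only the final
        # class, not the per-variant codes
        by_gene["MUTYH"].key: {"PS3": M, "PM1": M, "PM3": M, "PP4": M},
        by_gene["CTC1"].key: {"PP5": M},
        by_gene["PPARG"].key: {"PM1": M, "PP2": M},
        by_gene["DCC"].key: {"PM1": M, "PM2": M, "PP2": M},
    }
    expected_roman = {
        by_gene["PPARG"].key: "IV", by_gene["MUTYH"].key: "V",
        by_gene["POLN"].key: "V", by_gene["CTC1"].key: "V",
        by_gene["ALPK1"].key: "IV", by_gene["DCC"].key: "IV",
        by_gene["ATM"].key: "V", by_gene["ST18"].key: "IV",
    }
    patients = (
        Patient(id="1194", sex=Sex.FEMALE, tumors=(("ovary", 44),),
                ihc_loss=frozenset(), msi=MsiStatus.MSI,
                mlh1_methylated=Methylation.YES, braf_v600e=BrafStatus.UNTESTED,
                criteria=ClinicalCriteria.REVISED_BETHESDA),
        Patient(id="142", sex=Sex.MALE, tumors=(("colorectal", 39),),
                ihc_loss=frozenset({"MLH1", "PMS2", "MSH6"}), msi=MsiStatus.MSI,
                mlh1_methylated=Methylation.NO, braf_v600e=BrafStatus.WILDTYPE,
                criteria=ClinicalCriteria.BETHESDA),
        Patient(id="1728", sex=Sex.MALE, tumors=(("colorectal", 57),),
                ihc_loss=frozenset({"PMS2"}), msi=MsiStatus.MSI,
                criteria=ClinicalCriteria.REVISED_BETHESDA),
        Patient(id="313", sex=Sex.FEMALE, tumors=(("colorectal", 48),),
                ihc_loss=frozenset({"MSH6"}), msi=MsiStatus.MSI,
                criteria=ClinicalCriteria.REVISED_BETHESDA),
        Patient(id="573", sex=Sex.FEMALE, tumors=(("stomach", 44), ("colorectal", 49)),
                ihc_loss=frozenset({"MLH1", "PMS2"}), msi=MsiStatus.MSI,
                mlh1_methylated=Methylation.YES, braf_v600e=BrafStatus.WILDTYPE,
                criteria=ClinicalCriteria.BETHESDA),
        Patient(id="635", sex=Sex.MALE, tumors=(("colorectal", 50), ("non_melanoma_skin", 56)),
                ihc_loss=frozenset({"PMS2", "MSH6"}), msi=MsiStatus.MSI,
                criteria=ClinicalCriteria.REVISED_BETHESDA),
        Patient(id="837", sex=Sex.FEMALE, tumors=(("endometrium", 53), ("breast", 58)),
                ihc_loss=frozenset({"MLH1", "PMS2"}), msi=MsiStatus.MSI,
                mlh1_methylated=Methylation.YES, braf_v600e=BrafStatus.WILDTYPE,
                criteria=ClinicalCriteria.REVISED_BETHESDA),
    )
    panel_symbols = frozenset(
        {x.gene for x in v}
        | {"MLH1", "MSH2", "MSH6", "PMS2", "EPCAM", "POLE", "POLD1", "MSH3",
           "CHEK2", "RAD51B", "NTHL1", "POLH"}
    )
    return Table2Fixture(
        variants=tuple(v),
        patients=patients,
        panel=GenePanel(symbols=panel_symbols),
        lof_mechanism_genes=frozenset({"POLN", "CTC1", "ALPK1", "ATM", "ST18"}),
        manual_codes=manual_codes,
        expected_roman=expected_roman,
    )
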