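"""Input/output for annotated germline variants, gene panels and reports.

Variants arrive as annotated VCF 4.2 (one sample per file, annotations in
INFO under a declared key dialect) or as an equivalent flat TSV.  Readers
normalize every record into :class:`AnnotatedVariant`, the single in-memory
representation the rest of the pipeline consumes: multi-allelic records are
split per alternate allele, indels are reduced to their minimal
representation, and missing annotations map to explicit "absent" values.
"""

from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class LlskitError(Exception):
    """Base class for all package errors."""


class VcfParseError(LlskitError):
    pass


class ValidationError(LlskitError):
    pass


class HgvsParseError(LlskitError):
    """Raised for HGVS syntax outside the supported subset."""


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class ClinSig(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


class SpliceVerdict(str, enum.Enum):
    IMPACT = "impact"
    NO_IMPACT = "no_impact"
    ABSENT = "absent"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"


#: aliases accepted when parsing ClinVar/InterVar assertion strings
_CLINSIG_ALIASES: dict[str, ClinSig] = {
    "pathogenic": ClinSig.PATHOGENIC,
    "likely_pathogenic": ClinSig.LIKELY_PATHOGENIC,
    "likely pathogenic": ClinSig.LIKELY_PATHOGENIC,
    "uncertain_significance": ClinSig.VUS,
    "uncertain significance": ClinSig.VUS,
    "vus": ClinSig.VUS,
    "likely_benign": ClinSig.LIKELY_BENIGN,
    "likely benign": ClinSig.LIKELY_BENIGN,
    "benign": ClinSig.BENIGN,
    "conflicting": ClinSig.CONFLICTING,
    "conflicting_interpretations_of_pathogenicity": ClinSig.CONFLICTING,
    "conflicting_classifications_of_pathogenicity": ClinSig.CONFLICTING,
    "absent": ClinSig.ABSENT,
    ".": ClinSig.ABSENT,
    "": ClinSig.ABSENT,
}


def parse_clinsig(value: str | None) -> ClinSig:
    if value is None:
        return ClinSig.ABSENT
    key = value.strip().lower()
    try:
        return _CLINSIG_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unrecognized clinical-significance value: {value!r}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One normalized, annotation-bearing germline variant call.

    ``pos`` is 1-based as in VCF; ``ref``/``alt`` are minimal (no shared
    prefix/suffix beyond the VCF anchor base).  ``pop_af`` maps population
    database names (e.g. ``gnomad``, ``abraom``) to allele frequencies;
    databases the variant is absent from simply have no entry.
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    depth: int
    vaf: float
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    pop_af: Mapping[str, float] = field(default_factory=dict)
    clinvar: ClinSig = ClinSig.ABSENT
    intervar: ClinSig = ClinSig.ABSENT
    revel: float | None = None
    mcap: float | None = None
    splice_verdict: SpliceVerdict = SpliceVerdict.ABSENT
    zygosity: Zygosity = Zygosity.HET
    manual_review: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValidationError(f"{name} must be nonempty over ACGT, got {allele!r}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf out of [0,1]: {self.vaf}")
        for db, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(f"pop_af[{db}] out of [0,1]: {af}")
        for name, score in (("revel", self.revel), ("mcap", self.mcap)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValidationError(f"{name} out of [0,1]: {score}")

    @property
    def key(self) -> str:
        """Stable per-call identifier: patient:chrom:pos:ref:alt."""
        return f"{self.patient_id}:{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def variant_key(self) -> str:
        """Patient-independent identifier: chrom:pos:ref:alt."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenePanel:
    """A set of gene symbols restricting the analysis, case-normalized."""

    symbols: frozenset[str]
    source_tags: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError("gene panel is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfDialect:
    """Names of the INFO/FORMAT keys carrying each annotation.

    The defaults define this artifact's own dialect; annotations produced by
    other tools can be ingested by remapping the key names.
    """

    gene: str = "GENE"
    transcript: str = "TRANSCRIPT"
    hgvs_c: str = "HGVSC"
    hgvs_p: str = "HGVSP"
    consequence: str = "CSQ_CLASS"
    clinvar: str = "CLNSIG"
    intervar: str = "INTERVAR"
    revel: str = "REVEL"
    mcap: str = "MCAP"
    splice: str = "HSF"
    # population AF INFO key -> database name in AnnotatedVariant.pop_af
    pop_af_keys: Mapping[str, str] = field(
        default_factory=lambda: {"AF_GNOMAD": "gnomad", "AF_ABRAOM": "abraom"}
    )


def _round6g(x: float) -> float:
    # htslib stores INFO floats as float32; renormalizing to 6 significant
    # digits makes write->read round-trips exact for <=6-sig-fig annotations
    return float(f"{x:.6g}")


def minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix so indels are minimally represented."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _alt_value(value, index: int):
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    return value


def _info_get(info, key: str):
    # pysam raises ValueError for keys missing from the header; treat any
    # undeclared dialect key as an absent annotation
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None


def read_annotated_vcf(
    path: str | Path, dialect: VcfDialect | None = None
) -> list[AnnotatedVariant]:
    """Read an annotated single-sample VCF into AnnotatedVariant records.

    Multi-allelic records are split, one variant per alternate allele; the
    VAF is taken from the sample ``VAF`` field when present, otherwise
    computed as ``AD[alt] / DP`` (``DP`` falling back to ``sum(AD)``).
    """
    d = dialect or VcfDialect()
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    if not list(vf.header.samples):
        raise VcfParseError(f"{path}: VCF has no sample column")
    sample_name = list(vf.header.samples)[0]

    out: list[AnnotatedVariant] = []
    try:
        records = list(vf)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF record: {exc}") from exc
    for rec in records:
        sample = rec.samples[sample_name]
        alts = rec.alts or ()
        for i, alt in enumerate(alts):
            if alt is None or alt in ("*", "<NON_REF>"):
                continue
            try:
                out.append(_variant_from_record(rec, sample, i, alt, d))
            except ValidationError as exc:
                raise ValidationError(
                    f"{path} at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return out


def _variant_from_record(rec, sample, i: int, alt: str, d: VcfDialect) -> AnnotatedVariant:
    info = rec.info
    ad = sample.get("AD")
    depth = sample.get("DP")
    if depth is None and ad is not None:
        depth = sum(a for a in ad if a is not None)
    if depth is None:
        depth = _info_get(rec.info, "DP") or 0
    vaf = _alt_value(sample.get("VAF"), i)
    if vaf is None:
        if ad is None or depth in (None, 0):
            raise ValidationError("neither VAF nor AD/DP available to compute VAF")
        vaf = ad[i + 1] / depth
    gt = sample.get("GT")
    zyg = Zygosity.HOM if gt is not None and set(a for a in gt if a is not None) == {i + 1} else Zygosity.HET

    def s(key: str) -> str:
        v = _alt_value(_info_get(info, key), i)
        return "" if v in (None, ".") else str(v)

    def f(key: str) -> float | None:
        v = _alt_value(_info_get(info, key), i)
        if v in (None, "."):
            return None
        return _round6g(float(v))

    pop_af = {}
    for key, db in d.pop_af_keys.items():
        v = f(key)
        if v is not None:
            pop_af[db] = v

    csq = s(d.consequence)
    splice = s(d.splice)
    pos, ref, alt = minimal_representation(rec.pos, rec.ref, alt)
    return AnnotatedVariant(
        patient_id=sample.name,
        chrom=rec.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=s(d.gene),
        transcript=s(d.transcript),
        hgvs_c=s(d.hgvs_c),
        hgvs_p=s(d.hgvs_p),
        consequence=Consequence(csq) if csq else Consequence.OTHER,
        depth=int(depth),
        vaf=_round6g(float(vaf)),
        pop_af=pop_af,
        clinvar=parse_clinsig(s(d.clinvar) or None),
        intervar=parse_clinsig(s(d.intervar) or None),
        revel=f(d.revel),
        mcap=f(d.mcap),
        splice_verdict=SpliceVerdict(splice) if splice else SpliceVerdict.ABSENT,
        zygosity=zyg,
    )


def write_annotated_vcf(
    variants: Sequence[AnnotatedVariant],
    path: str | Path,
    dialect: VcfDialect | None = None,
) -> None:
    """Write variants of a single patient back to an annotated VCF 4.2."""
    d = dialect or VcfDialect()
    patients = {v.patient_id for v in variants}
    if len(patients) > 1:
        raise ValidationError(f"one VCF per patient: got {sorted(patients)}")
    sample = patients.pop() if patients else "SAMPLE"

    header = pysam.VariantHeader()
    for chrom in sorted({v.chrom for v in variants}, key=_chrom_sort_key):
        header.contigs.add(chrom)
    str_keys = [d.gene, d.transcript, d.hgvs_c, d.hgvs_p, d.consequence,
                d.clinvar, d.intervar, d.splice]
    for key in str_keys:
        header.info.add(key, 1, "String", f"{key} annotation")
    for key in (d.revel, d.mcap, *d.pop_af_keys):
        header.info.add(key, 1, "Float", f"{key} annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("VAF", 1, "Float", "Variant allele fraction")
    header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            info_vals = {
                d.gene: v.gene, d.transcript: v.transcript,
                d.hgvs_c: v.hgvs_c, d.hgvs_p: v.hgvs_p,
                d.consequence: v.consequence.value,
                d.clinvar: None if v.clinvar is ClinSig.ABSENT else v.clinvar.value,
                d.intervar: None if v.intervar is ClinSig.ABSENT else v.intervar.value,
                d.splice: None if v.splice_verdict is SpliceVerdict.ABSENT else v.splice_verdict.value,
                d.revel: v.revel, d.mcap: v.mcap,
            }
            for key, db in d.pop_af_keys.items():
                info_vals[key] = v.pop_af.get(db)
            for key, val in info_vals.items():
                if val not in (None, ""):
                    rec.info[key] = val
            rec.samples[sample]["GT"] = (1, 1) if v.zygosity is Zygosity.HOM else (0, 1)
            rec.samples[sample]["DP"] = v.depth
            rec.samples[sample]["VAF"] = v.vaf
            out.write(rec)


def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


# ---------------------------------------------------------------------------
# Flat TSV variant tables (the "equivalent flat TSV" input/exchange format)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "transcript",
    "hgvs_c", "hgvs_p", "consequence", "depth", "vaf", "pop_af", "clinvar",
    "intervar", "revel", "mcap", "splice_verdict", "zygosity", "manual_review",
]


def write_variants_tsv(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write variants as a flat TSV (pop_af serialized as db=af;db=af)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for v in sorted(variants, key=lambda v: (v.patient_id, _chrom_sort_key(v.chrom), v.pos, v.alt)):
            w.writerow([
                v.patient_id, v.chrom, v.pos, v.ref, v.alt, v.gene,
                v.transcript, v.hgvs_c, v.hgvs_p, v.consequence.value,
                v.depth, f"{v.vaf:.6g}",
                ";".join(f"{db}={af:.6g}" for db, af in sorted(v.pop_af.items())),
                v.clinvar.value, v.intervar.value,
                "" if v.revel is None else f"{v.revel:.6g}",
                "" if v.mcap is None else f"{v.mcap:.6g}",
                v.splice_verdict.value, v.zygosity.value,
                "yes" if v.manual_review else "no",
            ])


def read_variants_tsv(path: str | Path) -> list[AnnotatedVariant]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(_TSV_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(f"{path}: missing variant TSV columns")
        out = []
        for row in reader:
            pop_af = {}
            if row["pop_af"]:
                for pair in row["pop_af"].split(";"):
                    db, af = pair.split("=")
                    pop_af[db] = float(af)
            out.append(AnnotatedVariant(
                patient_id=row["patient_id"], chrom=row["chrom"],
                pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                gene=row["gene"], transcript=row["transcript"],
                hgvs_c=row["hgvs_c"], hgvs_p=row["hgvs_p"],
                consequence=Consequence(row["consequence"]),
                depth=int(row["depth"]), vaf=float(row["vaf"]), pop_af=pop_af,
                clinvar=ClinSig(row["clinvar"]), intervar=ClinSig(row["intervar"]),
                revel=float(row["revel"]) if row["revel"] else None,
                mcap=float(row["mcap"]) if row["mcap"] else None,
                splice_verdict=SpliceVerdict(row["splice_verdict"]),
                zygosity=Zygosity(row["zygosity"]),
                manual_review=row["manual_review"] == "yes",
            ))
    return out


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a newline-delimited gene symbol list, optional tab-separated tags.

    Symbols are upper-cased; duplicates are collapsed with a warning.
    """
    symbols: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            symbol = parts[0].strip().upper()
            tags = {t.strip() for t in parts[1].split(",")} if len(parts) > 1 else set()
            if symbol in symbols:
                logger.warning("duplicate panel symbol %s collapsed", symbol)
                symbols[symbol] |= tags
            else:
                symbols[symbol] = tags
    if not symbols:
        raise ValidationError(f"{path}: empty gene panel")
    logger.info("gene panel loaded: %d symbols", len(symbols))
    return GenePanel(
        symbols=frozenset(symbols),
        source_tags={s: frozenset(t) for s, t in symbols.items() if t},
    )


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(panel.symbols):
            tags = panel.source_tags.get(symbol)
            fh.write(symbol + ("\t" + ",".join(sorted(tags)) if tags else "") + "\n")


def write_report(result, path) -> None:
    """Write the final cohort report TSV (delegates to :mod:`llskit.cohort`)."""
    from .cohort import write_report as _write_report

    _write_report(result, path)


# ---------------------------------------------------------------------------
# HGVS coding-level subset parser
# ---------------------------------------------------------------------------

class HgvsKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    DELINS = "delins"
    INTRONIC_SUBSTITUTION = "intronic_substitution"


@dataclass(frozen=True)
class HgvsDescriptor:
    """Parsed c.-level HGVS for the supported subset.

    Supported: substitutions (incl. intronic offsets), deletions,
    duplications and delins over positive coding coordinates.  ``offset``
    and ``end_offset`` are intronic offsets (0 for exonic positions).
    """

    kind: HgvsKind
    start: int
    transcript: str = ""
    offset: int = 0
    end: int | None = None
    end_offset: int = 0
    ref_allele: str = ""
    alt_allele: str = ""

    def __str__(self) -> str:
        prefix = f"{self.transcript}:" if self.transcript else ""
        pos = f"{self.start}{_fmt_offset(self.offset)}"
        if self.end is not None:
            pos += f"_{self.end}{_fmt_offset(self.end_offset)}"
        if self.kind in (HgvsKind.SUBSTITUTION, HgvsKind.INTRONIC_SUBSTITUTION):
            return f"{prefix}c.{pos}{self.ref_allele}>{self.alt_allele}"
        if self.kind is HgvsKind.DELETION:
            return f"{prefix}c.{pos}del{self.ref_allele}"
        if self.kind is HgvsKind.DUPLICATION:
            return f"{prefix}c.{pos}dup{self.ref_allele}"
        return f"{prefix}c.{pos}delins{self.alt_allele}"


def _fmt_offset(offset: int) -> str:
    return f"{offset:+d}" if offset else ""


_HGVS_PREFIX_RE = re.compile(
    r"^(?:(?P<chrom_acc>N[CG]_\d+\.\d+)\()?(?P<tx>[A-Z]+_?\d+\.\d+)\)?:$"
)
_POS_RE = r"(?P<{0}>\d+)(?P<{0}off>[+-]\d+)?"
_HGVS_BODY_RE = re.compile(
    r"^c\."
    + _POS_RE.format("start")
    + r"(?:_" + _POS_RE.format("end") + r")?"
    + r"(?:"
    r"(?P<sub>(?P<ref>[ACGT])>(?P<alt>[ACGT]))"
    r"|(?P<delins>delins(?P<insalleles>[ACGT]+))"
    r"|(?P<del>del(?P<delalleles>[ACGT]*))"
    r"|(?P<dup>dup(?P<dupalleles>[ACGT]*))"
    r")$"
)


def parse_hgvs_c(s: str) -> HgvsDescriptor:
    """Parse a coding-level HGVS string from the supported subset.

    Accepts an optional ``TRANSCRIPT:`` prefix, also in the
    ``NC_...(NM_...):`` genomic-wrapper form (the wrapper accession is
    dropped on normalization).  Anything outside the subset raises
    :class:`HgvsParseError` rather than misparsing silently.
    """
    compact = re.sub(r"\s+", "", s)
    transcript = ""
    if ":" in compact:
        prefix, _, body = compact.rpartition(":")
        m = _HGVS_PREFIX_RE.match(prefix + ":")
        if not m:
            raise HgvsParseError(f"unsupported transcript prefix in {s!r}")
        transcript = m.group("tx")
    else:
        body = compact
    m = _HGVS_BODY_RE.match(body)
    if not m:
        raise HgvsParseError(f"unsupported HGVS syntax: {s!r}")
    start = int(m.group("start"))
    if start < 1:
        raise HgvsParseError(f"coding coordinate must be >= 1 in {s!r}")
    offset = int(m.group("startoff") or 0)
    end = int(m.group("end")) if m.group("end") else None
    end_offset = int(m.group("endoff") or 0)
    if end is not None and (end, end_offset) < (start, offset):
        raise HgvsParseError(f"range end precedes start in {s!r}")

    if m.group("sub"):
        if end is not None:
            raise HgvsParseError(f"substitution cannot span a range: {s!r}")
        if m.group("ref") == m.group("alt"):
            raise HgvsParseError(f"reference equals alternate in {s!r}")
        kind = (
            HgvsKind.INTRONIC_SUBSTITUTION if offset else HgvsKind.SUBSTITUTION
        )
        return HgvsDescriptor(
            kind=kind, start=start, transcript=transcript, offset=offset,
            ref_allele=m.group("ref"), alt_allele=m.group("alt"),
        )
    if m.group("delins"):
        return HgvsDescriptor(
            kind=HgvsKind.DELINS, start=start, transcript=transcript,
            offset=offset, end=end, end_offset=end_offset,
            alt_allele=m.group("insalleles"),
        )
    if m.group("del"):
        return HgvsDescriptor(
            kind=HgvsKind.DELETION, start=start, transcript=transcript,
            offset=offset, end=end, end_offset=end_offset,
            ref_allele=m.group("delalleles"),
        )
    return HgvsDescriptor(
        kind=HgvsKind.DUPLICATION, start=start, transcript=transcript,
        offset=offset, end=end, end_offset=end_offset,
        ref_allele=m.group("dupalleles"),
    )
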