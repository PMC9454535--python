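# llskit

Germline variant prioritization, ACMG/AMP classification and cohort
statistics for Lynch-like syndrome (LLS) gene-panel analyses.

## The problem

Lynch syndrome is the most common hereditary colorectal cancer syndrome,
caused by germline pathogenic variants in the mismatch-repair (MMR) genes
(*MLH1*, *MSH2*, *MSH6*, *PMS2*) or *EPCAM* deletions. A substantial
fraction of patients meet the clinical criteria and show tumor MMR
deficiency (IHC protein loss and/or microsatellite instability) yet carry
no detectable MMR germline variant — Lynch-**like** syndrome. Finding
candidate predisposing variants in these patients means sifting
exome-scale germline calls over a curated cancer/DNA-repair gene panel
down to a handful worth manual ACMG review.

`llskit` implements that workflow as a tested, reusable pipeline:

1. **Triage** — clinical eligibility from the IHC loss pattern: tumors
   losing PMS2/MSH2/MSH6 go to germline testing directly; MLH1-deficient
   tumors are gated on BRAF p.(Val600Glu) (wild-type → test, regardless of
   *MLH1* promoter methylation; mutant → sporadic, no test).
2. **Prioritization cascade** — per variant, in order: depth ≥ 30 reads,
   VAF ≥ 25 %, population MAF ≤ 1 % in every declared database (gnomAD,
   ABraOM), panel membership; survivors are routed for classification if
   they are reported pathogenic (ClinVar/InterVar), loss-of-function
   (nonsense, frameshift, canonical splice site), or VUS with in-silico
   support (REVEL > 0.7 or M-CAP > 0.025 for missense; a splice-impact
   verdict for splicing candidates). Every variant gets exactly one
   audited disposition.
3. **ACMG classification** — automatic evidence codes (PVS1, PM2, PP3,
   BP4, BA1, BS1) merged with manually curated codes, combined by the
   2015 ACMG/AMP rules into tiers I–V (benign … pathogenic).
4. **Cohort statistics** — class shares, carrier rate (≥ 1 class IV/V
   variant), ANOVA for ages, Kruskal–Wallis for tumor counts, chi-square
   or Fisher's exact test for 2×2 tables of carrier status vs tumor
   features.

A seeded synthetic-cohort generator plants variants of known category
(removable: common / low-depth / low-VAF / off-panel / unsupported VUS;
retainable: rare LoF / reported pathogenic / high-score missense /
splice-impact) so the whole pipeline is testable without patient data.

## Worked example

The package ships a fixture of eight published class IV/V variants from a
20-patient LLS cohort (seven patients; genomic coordinates and curation
codes are labelled reconstructions). Running the cascade and the
classifier over it:

```python
from llskit import (
    FilterConfig, classify_selected, prioritize,
    summarize_cohort, table2_fixture,
)

fx = table2_fixture()
dispositions = prioritize(fx.variants, fx.panel, FilterConfig())
classified = classify_selected(
    dispositions, fx.lof_mechanism_genes, fx.manual_codes)
result = summarize_cohort(fx.patients, classified)

for cv in classified:
    v = cv.variant
    print(f"{v.patient_id:>5} {v.gene:<6} {v.hgvs_c:<15} "
          f"{cv.route.value:<19} {cv.acmg.roman}")
print(f"carriers: {result.n_carriers}/{len(result.patients)} "
      f"({result.carrier_rate_pct}%)")
```

prints

```
 1194 PPARG  c.1230C>A       insilico_missense   IV
  142 MUTYH  c.1187G>A       reported_pathogenic V
 1728 POLN   c.1375-2A>G     lof                 V
  313 CTC1   c.19C>T         lof                 V
  573 ALPK1  c.3428_3431del  lof                 IV
  635 DCC    c.1861G>A       insilico_splice     IV
  837 ATM    c.3993+1G>A     lof                 V
  837 ST18   c.2093del       lof                 IV
```

Each row is one retained variant with its routing reason and ACMG tier:
all eight survive the cascade, four classify as pathogenic (V) and four
as likely pathogenic (IV); every one of these seven patients is a carrier
(`7/7`), since all harbor a class IV/V variant.

The same stages run from the shell:

```bash
llskit run-all --seed 7 --out results/      # synthetic end-to-end demo
llskit simulate --seed 7 --out cohort/
llskit prioritize --vcf cohort/P001.vcf --panel cohort/panel.txt \
    --out selected.tsv --audit audit.tsv
llskit classify --selected selected.tsv --lof-genes cohort/lof_mechanism_genes.txt \
    --out classified.tsv
llskit stats --pheno cohort/phenotypes.tsv --classified classified.tsv \
    --out summary.json
```

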