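import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from llskit.io import (
    AnnotatedVariant,
    ClinSig,
    Consequence,
    GenePanel,
    SpliceVerdict,
    Zygosity,
)
from llskit.synthetic_cohort import SimConfig, generate_cohort, table2_fixture

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_t2():
    """The eight published class IV/V variants with reconstructed curation."""
    return table2_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20-patient synthetic cohort (seed 0)."""
    return generate_cohort(SimConfig())


@pytest.fixture(scope="session")
def small_panel():
    return GenePanel(symbols=frozenset({"MUTYH", "ATM", "POLN", "GENEA", "GENEB"}))


def random_variant(rng: np.random.Generator, i: int) -> AnnotatedVariant:
    """Random variant hitting filter boundaries often (for oracle tests)."""
    consequence = Consequence(
        str(rng.choice([c.value for c in Consequence]))
    )
    ref, alt = ("A", "G") if consequence not in (
        Consequence.FRAMESHIFT_INDEL, Consequence.INFRAME_INDEL
    ) else ("AGT", "A")
    pop_af = {}
    for db in ("gnomad", "abraom"):
        if rng.random() < 0.6:
            pop_af[db] = float(rng.choice([0.0, 0.005, 0.0099, 0.01, 0.0101, 0.02, 0.06]))
    return AnnotatedVariant(
        patient_id="PX",
        chrom=str(rng.integers(1, 23)),
        pos=1000 + i,
        ref=ref,
        alt=alt,
        gene=str(rng.choice(["MUTYH", "ATM", "POLN", "GENEA", "GENEB", "TTN", "OFFX"])),
        consequence=consequence,
        depth=int(rng.choice([0, 10, 29, 30, 31, 100])),
        vaf=float(rng.choice([0.0, 0.1, 0.249, 0.25, 0.251, 0.5, 1.0])),
        pop_af=pop_af,
        clinvar=ClinSig(str(rng.choice([c.value for c in ClinSig]))),
        intervar=ClinSig(str(rng.choice([c.value for c in ClinSig]))),
        revel=None if rng.random() < 0.3 else float(rng.choice([0.1, 0.69, 0.7, 0.71, 0.9])),
        mcap=None if rng.random() < 0.5 else float(rng.choice([0.01, 0.024, 0.025, 0.026, 0.2])),
        splice_verdict=SpliceVerdict(
            str(rng.choice([s.value for s in SpliceVerdict], p=[0.25, 0.25, 0.5]))
        ),
        zygosity=Zygosity.HET,
    )


def random_variants(n: int, seed: int) -> list[AnnotatedVariant]:
    rng = np.random.default_rng(seed)
    return [random_variant(rng, i) for i in range(n)]
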