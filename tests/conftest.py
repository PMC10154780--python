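import numpy as np
import pytest

from congmap.models import (
    GenomicInterval,
    Genotype,
    Phenotype,
    Role,
    StrainEntry,
    StrainPanel,
    VariantCall,
)
from congmap.simulate import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def panel4() -> StrainPanel:
    return StrainPanel(
        [
            StrainEntry("CBA", Phenotype.PRONE, Role.DONOR_PARENT),
            StrainEntry("AKR", Phenotype.RESISTANT, Role.RECIPIENT_PARENT),
            StrainEntry("HT76", Phenotype.PRONE, Role.DERIVED),
            StrainEntry("ASC", Phenotype.PRONE, Role.DERIVED),
        ]
    )


@pytest.fixture(scope="session")
def sim_noise_free():
    return simulate_cross(
        SimConfig(seed=202, genotype_error_rate=0.0, missing_rate=0.0)
    )


@pytest.fixture(scope="session")
def sim_default():
    return simulate_cross(SimConfig(seed=11))


GT_CODES = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]


def random_calls(rng, n, strains, chrom="13", span=10_000_000):
    """Random biallelic calls with uniform genotype states."""
    pos = np.sort(rng.choice(span, size=n, replace=False)) + 1
    codes = rng.integers(0, 4, size=(n, len(strains)))
    bases = "ACGT"
    calls = []
    for i in range(n):
        r = bases[int(rng.integers(0, 4))]
        a = bases[int(rng.integers(0, 4))]
        while a == r:
            a = bases[int(rng.integers(0, 4))]
        calls.append(
            VariantCall(
                chrom,
                int(pos[i]),
                r,
                a,
                {s: GT_CODES[int(codes[i, k])] for k, s in enumerate(strains)},
                var_id=f"r{i:05d}",
            )
        )
    return calls


def make_marker_calls(positions, is_donor_state, derived="HT76", orient=None, rng=None):
    """Informative marker calls for one derived strain.

    ``orient[i]`` True -> donor-specific marker (donor allele = hom_alt),
    False -> recipient-specific (donor allele = hom_ref); random if None.
    ``is_donor_state[i]`` sets the derived strain's local origin; None
    entries become ambiguous (het) calls.
    """
    rng = rng or np.random.default_rng(0)
    if orient is None:
        orient = rng.random(len(positions)) < 0.5
    calls = []
    for k, (p, st) in enumerate(zip(positions, is_donor_state)):
        donor_is_alt = bool(orient[k])
        d = Genotype.HOM_ALT if donor_is_alt else Genotype.HOM_REF
        r = Genotype.HOM_REF if donor_is_alt else Genotype.HOM_ALT
        if st is None:
            g = Genotype.HET
        else:
            g = d if st else r
        calls.append(
            VariantCall(
                "13",
                int(p),
                "A",
                "G",
                {"CBA": d, "AKR": r, derived: g, "ASC": g},
                var_id=f"m{k:05d}",
            )
        )
    return calls


@pytest.fixture
def toy_locus():
    return GenomicInterval("13", 1_000_000, 2_000_000)
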