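import numpy as np
import pandas as pd
import pytest

from pxdscout.genome import GeneModel, ReferenceAssembly
from pxdscout.simulate import SyntheticScenario, generate_scenario


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def tiny_assembly():
    """1 kb contig with a fixed codon 133 = ACC inside the plus-strand gene CDS."""
    rng = np.random.default_rng(1234)
    seq = list(_random_dna(rng, 1000))
    # gene CDS occupies [100, 700); codon 133 occupies CDS offsets 396..398
    seq[100 + 396: 100 + 399] = list("ACC")
    return ReferenceAssembly({"chrT": "".join(seq)})


@pytest.fixture(scope="session")
def plus_gene():
    """Single-exon plus-strand gene whose first coding base is genomic 101 (1-based)."""
    return GeneModel("geneP", "chrT", "+", ((100, 700),), 100, 700)


@pytest.fixture(scope="session")
def minus_gene_assembly():
    """Two-exon minus-strand gene with its assembly; CDS length 300."""
    rng = np.random.default_rng(99)
    seq = _random_dna(rng, 600)
    assembly = ReferenceAssembly({"chrM": seq})
    gene = GeneModel("geneM", "chrM", "-", ((100, 250), (350, 500)), 100, 500)
    return assembly, gene


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced synthetic study for fast end-to-end tests."""
    scenario = SyntheticScenario(
        seed=202, n_genes=10, contig_length=20_000, n_controls=8,
        het_coding_per_genome=40, hom_coding_per_genome=60,
        hom_noncoding_per_genome=40,
    )
    return generate_scenario(scenario)


def paper_cohort_frame() -> pd.DataFrame:
    """The published genotyping cohort as an explicit genotype table:
    25 affected homozygotes (22 SCWT + 3 Whoodles), 682 control SCWT with
    15 heterozygotes and 667 reference homozygotes, 388 Poodles and 132
    other-breed dogs all homozygous reference."""
    rows = (
        [("SCWT", "affected", "hom_alt")] * 22
        + [("Whoodle", "affected", "hom_alt")] * 3
        + [("SCWT", "unaffected", "het")] * 15
        + [("SCWT", "unaffected", "hom_ref")] * 667
        + [("Poodle", "unaffected", "hom_ref")] * 388
        + [("other", "unaffected", "hom_ref")] * 132
    )
    df = pd.DataFrame(rows, columns=["breed", "phenotype", "genotype"])
    df.insert(0, "sample_id", [f"d{i:04d}" for i in range(len(df))])
    return df


@pytest.fixture(scope="session")
def paper_cohort():
    return paper_cohort_frame()
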