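import numpy as np
import pandas as pd
import pytest

import divscan as ds
from divscan.synth import default_snp_layout


@pytest.fixture(scope="session")
def bn_cohort():
    """Six drifted breeds, 2000 SNPs: shared input for FST/QC-level tests."""
    configs = [ds.BreedSimConfig(f"BR{i + 1}", 50, 0.1) for i in range(6)]
    return ds.simulate_balding_nichols(configs, n_snps=2000, seed=11)


@pytest.fixture(scope="session")
def genedrop_cohort():
    """Random-mating pedigree over few founders gene-dropped at 50-kb
    spacing, with the true autozygous tracts."""
    ped = ds.simulate_pedigree(
        n_founders=12, generations=5, offspring_per_generation=30,
        mating="random", seed=7,
    )
    layout = default_snp_layout(n_snps=8000, n_chromosomes=4, spacing_bp=50_000)
    cohort, truth = ds.gene_drop(ped, layout, seed=8)
    return cohort, truth, ped


@pytest.fixture
def tiny_plink(tmp_path):
    """Hand-written 2-individual, 3-SNP PED/MAP pair with one missing call."""
    map_path = tmp_path / "toy.map"
    ped_path = tmp_path / "toy.ped"
    map_path.write_text(
        "1\tsnp1\t0\t1000\n"
        "1\tsnp2\t0\t2000\n"
        "2\tsnp3\t0\t1500\n"
    )
    ped_path.write_text(
        "FAM1 ind1 0 0 0 -9 A A A G 0 0\n"
        "FAM1 ind2 0 0 0 -9 A G G G C C\n"
    )
    return ped_path, map_path
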