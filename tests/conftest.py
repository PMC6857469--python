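import numpy as np
import pytest

from caseinhap import genotype_io as gio
from caseinhap import synthetic_data as sd
from caseinhap import tables


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Three-breed cohort with the full default 892-SNP category layout."""
    cfg = sd.SimConfig(
        breeds=[("DSN", 30), ("Holstein", 35), ("Jersey", 31)],
        seed=7,
        missing_rate=0.01,
    )
    return sd.simulate_cohort(cfg, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def default_matrix(default_bundle):
    matrix = gio.read_vcf(default_bundle.vcf_path)
    return gio.attach_breeds(
        matrix, gio.read_breed_map(default_bundle.breed_map_path))


@pytest.fixture()
def matrix(default_matrix):
    """Function-scoped mutable copy."""
    return default_matrix.copy()


@pytest.fixture(scope="session")
def gene_models(default_bundle):
    return default_bundle.gene_models


@pytest.fixture(scope="session")
def reference(default_bundle):
    return default_bundle.reference


@pytest.fixture(scope="session")
def core_only_bundle(tmp_path_factory):
    """Tiny fixture: just the seven defining SNPs, no fillers."""
    cfg = sd.SimConfig(
        breeds=[("DSN", 40), ("Holstein", 40)],
        seed=11,
        category_counts={"missense": len(tables.CORE_SNPS)},
    )
    return sd.simulate_cohort(cfg, tmp_path_factory.mktemp("core_only"))


@pytest.fixture(scope="session")
def core_only_matrix(core_only_bundle):
    matrix = gio.read_vcf(core_only_bundle.vcf_path)
    return gio.attach_breeds(
        matrix, gio.read_breed_map(core_only_bundle.breed_map_path))


def truth_dosage(bundle, breed=None):
    """Expected dosage at the defining SNPs from the phased truth table."""
    truth = bundle.truth if breed is None else bundle.truth[
        bundle.truth.breed == breed]
    positions = tables.core_positions()
    alt = {s.pos: s.alt for s in tables.CORE_SNPS}
    rows = []
    for rec in truth.itertuples():
        a1 = sd.expand_haplotype(rec.hap1)
        a2 = sd.expand_haplotype(rec.hap2)
        rows.append([int(a1[p] == alt[p]) + int(a2[p] == alt[p])
                     for p in positions])
    return np.array(rows)
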