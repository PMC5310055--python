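from dataclasses import dataclass

import numpy as np
import pytest

from tmau.cascade import CascadeReport, run_cascade
from tmau.catalog_network import (
    expand_seed_genes,
    interactome_variant_scan,
    lookup_known_variants,
)
from tmau.metabolic import profile_cohort
from tmau.synth import study_fixture
from tmau.variants import GenotypeMatrix, Sex, SubjectInfo, VariantKey, Zygosity


@pytest.fixture(scope="session")
def fixture():
    """The published-table fixture, built once per session."""
    return study_fixture()


@dataclass
class PipelineResult:
    profiles: list
    catalog_hits: list
    cascade: CascadeReport
    interactome_hits: set


@pytest.fixture(scope="session")
def pipeline(fixture):
    """All pipeline stages run once on the published-table fixture."""
    profiles = profile_cohort(fixture.urine_samples)
    hits = lookup_known_variants(fixture.matrix, fixture.catalog, fixture.extra_genotypes)
    cascade = run_cascade(fixture.matrix, fixture.annotations, fixture.oxidoreductase_genes)
    dmgdh = interactome_variant_scan(
        fixture.matrix,
        fixture.annotations,
        expand_seed_genes(fixture.network, ["DMGDH"]),
    )
    return PipelineResult(profiles, hits, cascade, dmgdh)


def make_matrix(cells, sexes=None, keys=None):
    """Build a small matrix from a list-of-lists of Zygosity values.

    Rows are subjects s1..sn (female unless ``sexes`` overrides), columns
    are autosomal SNVs at increasing positions unless ``keys`` overrides.
    """
    cells = np.asarray(cells, dtype=np.int8)
    n_subj, n_var = cells.shape
    sexes = sexes or [Sex.F] * n_subj
    subjects = [SubjectInfo(id=f"s{i + 1}", sex=sexes[i]) for i in range(n_subj)]
    keys = keys or [VariantKey("1", 1000 + j, "A", "G") for j in range(n_var)]
    return GenotypeMatrix(subjects=subjects, variants=keys, cells=cells)


@pytest.fixture
def toy_matrix():
    Z = Zygosity
    return make_matrix(
        [
            [Z.HET, Z.HET, Z.MISSING, Z.HOM_REF],
            [Z.HET, Z.HET, Z.HOM_ALT, Z.HOM_REF],
            [Z.HOM_ALT, Z.HET, Z.HOM_REF, Z.HOM_REF],
        ]
    )
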