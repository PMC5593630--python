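"""Shared fixtures: one default synthetic study reused across the suite.

The compendium, derived markers, and tumor cohort are session-scoped so
the expensive stages run once; seeds follow the pipeline convention
(master seed, cohort = master + 1).
"""

import pytest

import immunodissect as im

MASTER_SEED = 1


@pytest.fixture(scope="session")
def compendium_bundle():
    comp, programs, standards = im.generate_compendium(
        im.CompendiumConfig(seed=MASTER_SEED)
    )
    z = im.zscore_transform(comp)
    return comp, z, programs, standards


@pytest.fixture(scope="session")
def derived_markers(compendium_bundle):
    _, z, _, standards = compendium_bundle
    params = im.DerivationParams(seed=MASTER_SEED)
    return im.derive_all(z, {ct: standards[ct] for ct in im.LYMPHOCYTES}, params)


@pytest.fixture(scope="session")
def cohort_bundle(compendium_bundle):
    _, _, programs, _ = compendium_bundle
    cohort = im.generate_tumor_cohort(
        im.TumorCohortConfig(seed=MASTER_SEED + 1),
        {ct: programs[ct] for ct in im.LYMPHOCYTES},
    )
    z = im.zscore_transform(cohort.expression)
    return cohort, z


@pytest.fixture(scope="session")
def signatures(derived_markers):
    return {ct: ms.signature for ct, ms in derived_markers.items()}
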