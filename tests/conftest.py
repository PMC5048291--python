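
import pandas as pd
import pytest

from mutiface import (
    CohortSpec,
    InterfaceDef,
    ProteinRecord,
    generate_cohort,
    generate_contact_counts,
    generate_interface_catalog,
    generate_proteome,
    train_pair_potential,
)
from mutiface.synthetic import VARIANT_COLUMNS


@pytest.fixture(scope="session")
def random_table():
    """A trained pair potential with non-trivial log-odds of both signs."""
    return train_pair_potential(generate_contact_counts(seed=11))


@pytest.fixture(scope="session")
def uniform_table():
    counts = {
        (a, t): 5
        for a in "ACDEFGHIKLMNPQRSTVWY"
        for t in ("hydrophobic", "polar", "charged", "aromatic")
    }
    return train_pair_potential(counts, contact_types=tuple({t for _, t in counts}))


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(n_proteins=8, length=60, seed=5)


@pytest.fixture(scope="session")
def small_catalog(small_proteome):
    return generate_interface_catalog(
        small_proteome, n_interfaces=12, positions_per_interface=5, seed=7
    )


def make_cohort(
    proteome,
    catalog,
    n_samples=50,
    background_rate=1.0,
    planted=(),
    exclusive=(),
    seed=0,
    table=None,
    cancer_types=(("lung", "adenocarcinoma"),),
):
    spec = CohortSpec(
        n_samples=n_samples,
        cancer_types=list(cancer_types),
        background_rate=background_rate,
        planted_drivers=list(planted),
        exclusivity_pairs=list(exclusive),
        seed=seed,
    )
    return generate_cohort(proteome, catalog, spec, table=table)


@pytest.fixture
def cohort_factory(small_proteome, small_catalog, random_table):
    def factory(**kwargs):
        kwargs.setdefault("table", random_table)
        return make_cohort(small_proteome, small_catalog, **kwargs)

    return factory


def variants_frame(rows):
    """Build a variant frame from (sample, protein, pos, ref, alt) tuples."""
    recs = [
        dict(zip(VARIANT_COLUMNS, (*r, "lung", "adenocarcinoma")))
        for r in rows
    ]
    return pd.DataFrame(recs, columns=VARIANT_COLUMNS)


def simple_interface(iface_id, protein_id, positions, partner_class="protein",
                     identity=90.0, contact_types=("polar",)):
    return InterfaceDef(
        interface_id=iface_id,
        protein_id=protein_id,
        partner_id="PX",
        partner_class=partner_class,
        contacts={p: tuple(contact_types) for p in positions},
        template_identity=identity,
    )
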