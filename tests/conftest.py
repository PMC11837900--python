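import numpy as np
import pandas as pd
import pytest

from mixotroph.simulate import SimulationConfig, simulate_isotope_dataset


@pytest.fixture
def toy_isotope_frame() -> pd.DataFrame:
    """One plot, three references and one focal specimen per category."""
    rows = [
        ("ref1", "PopA", "P1", "AUTO_REF", -30.0, -2.0),
        ("ref2", "PopA", "P1", "AUTO_REF", -32.0, -1.0),
        ("ref3", "PopA", "P1", "AUTO_REF", -31.0, -2.4),
        ("rhz1", "PopA", "P1", "OP_RHIZOME", -27.6, 2.0),
        ("rts1", "PopA", "P1", "OP_ROOTS", -29.7, 1.3),
        ("pro1", "PopA", "P1", "OP_PROTOCORM", -24.3, -0.7),
    ]
    return pd.DataFrame(rows, columns=["specimen_id", "population", "plot_id",
                                       "category", "delta13C", "delta15N"])


@pytest.fixture
def toy_otu_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two OTUs x two samples, one mycorrhizal family and one mould."""
    otus = pd.DataFrame({
        "otu_id": ["Psath_OTU1", "Mort_OTU1"],
        "family": ["Psathyrellaceae", "Mortierellaceae"],
        "genus": ["Coprinopsis", "Mortierella"],
        "guild": ["SAPROTROPH_NONRHIZOCTONIA", "NON_MYCORRHIZAL"],
        "s1": [90, 10],
        "s2": [50, 50],
    })
    meta = pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "individual_id": ["i1", "i2"],
        "population": ["PopA", "PopA"],
        "morph": ["WITH_RHIZOME", "WITH_RHIZOME"],
        "organ": ["RHIZOME", "RHIZOME"],
    })
    return otus, meta


@pytest.fixture
def standards_frame() -> pd.DataFrame:
    """The two glycine/threonine laboratory standards, measured = known."""
    return pd.DataFrame({
        "name": ["CERKU-03", "CERKU-05"],
        "known_delta13C": [-34.92, -9.45],
        "known_delta15N": [2.18, -2.88],
        "measured_delta13C": [-34.92, -9.45],
        "measured_delta15N": [2.18, -2.88],
    })


@pytest.fixture(scope="session")
def default_dataset() -> tuple[pd.DataFrame, dict]:
    """One seeded draw from the default (noisy) study design."""
    return simulate_isotope_dataset(SimulationConfig(seed=20_240_101))
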