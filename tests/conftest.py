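import numpy as np
import pandas as pd
import pytest

from limnoch4 import SyntheticConfig
from limnoch4.community import OtuTable
from limnoch4.synthetic import (
    generate_core_chemistry,
    generate_flux_records,
    generate_otu_table,
    generate_qpcr_plate,
)


@pytest.fixture(scope="session")
def cfg():
    """Default study conditions, fixed seed."""
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def noise_free_cfg():
    return SyntheticConfig(
        seed=7,
        flux_noise_sdlog=0.0,
        isotope_noise_sd=0.0,
        activity_sdlog=0.0,
        DIC_noise_sdlog=0.0,
        qpcr_noise_sd_ct=0.0,
    )


@pytest.fixture(scope="session")
def flux_records(cfg):
    return generate_flux_records(cfg)


@pytest.fixture(scope="session")
def chemistry(cfg):
    return generate_core_chemistry(cfg)


@pytest.fixture(scope="session")
def otu_table(cfg):
    return generate_otu_table(cfg)


@pytest.fixture(scope="session")
def qpcr_plate(cfg):
    return generate_qpcr_plate(cfg)


@pytest.fixture()
def tiny_table():
    """Hand-built 4-sample, 3-OTU table for arithmetic oracles."""
    counts = pd.DataFrame(
        [[30, 2970, 0], [10, 2980, 10], [0, 2990, 10], [15, 2955, 30]],
        index=["s1", "s2", "s3", "s4"],
        columns=["OTU_a", "OTU_b", "OTU_c"],
    )
    taxonomy = pd.Series(
        {
            "OTU_a": "Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;Methanoregulaceae",
            "OTU_b": "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales",
            "OTU_c": "Bacteria;Proteobacteria;Deltaproteobacteria;Syntrophobacterales;Syntrophaceae",
        }
    )
    meta = pd.DataFrame(
        {
            "core": ["c1", "c1", "c2", "c2"],
            "lake": ["MH", "MH", "MH", "MH"],
            "zone": ["edge", "edge", "middle", "middle"],
            "depth_cm": [4.0, 8.0, 4.0, 8.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return OtuTable(counts, taxonomy, meta)


def random_distance_matrix(rng, n):
    """Euclidean distances of random points: a valid metric matrix."""
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=labels, columns=labels)
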