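import logging

import numpy as np
import pandas as pd
import pytest

from ibescape.genotypes import GenotypeMatrix, SampleTable

logging.getLogger("ibescape").setLevel(logging.ERROR)


def make_genotypes(dosage, depth=None, sample_prefix="s", locus_prefix="L"):
    """Build a GenotypeMatrix from a nested list (None -> missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in dosage]
    )
    n, m = arr.shape
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i+1}" for i in range(n)],
        locus_ids=[f"{locus_prefix}{j+1}" for j in range(m)],
        dosage=arr,
        depth=None if depth is None else np.array(depth, dtype=float),
    )


def make_samples(rows):
    """rows: list of (sample_id, locality, habitat[, lat, lon[, taxon]])."""
    recs = []
    for r in rows:
        sid, loc, hab = r[0], r[1], r[2]
        lat = r[3] if len(r) > 3 else 0.0
        lon = r[4] if len(r) > 4 else 0.0
        taxon = r[5] if len(r) > 5 else ""
        recs.append((sid, loc, hab, lat, lon, taxon))
    return SampleTable(
        pd.DataFrame(
            recs,
            columns=["sample_id", "locality", "habitat", "latitude", "longitude", "taxon"],
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulated dataset shared across tests (300 loci)."""
    import ibescape as ib

    cfg = ib.espeletia_config(
        seed=11, n_neutral_loci=260, n_habitat_loci=30, n_private_loci=10
    )
    G, S, truth = ib.simulate_dataset(cfg)
    return G, S, truth
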