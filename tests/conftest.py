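import numpy as np
import pytest

from ednaclock import io, sites, synthetic


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory):
    """The noise-free planted-trajectory dataset (session-shared)."""
    out = tmp_path_factory.mktemp("planted")
    return synthetic.generate_dataset(synthetic.planted_preset(seed=7), out)


def dataset_to_design(ds, dataset="full"):
    """Run the full site pipeline on a generated dataset."""
    records = []
    for (sample_id, submodel), path in ds.bedmethyl_paths.items():
        records.extend(io.read_bedmethyl(path, sample_id, submodel))
    recon = sites.reconcile_modtypes(records, ds.samples)
    covered = sites.filter_complete_coverage(recon.sites)
    aging = sites.detect_aging_sites(covered)
    intervals = io.read_genbank_features(ds.annotation_path)
    aging = sites.annotate_genes(aging, intervals)
    return sites.build_design_matrix(aging, dataset=dataset)


@pytest.fixture(scope="session")
def planted_design(planted_dataset):
    return dataset_to_design(planted_dataset)


@pytest.fixture(scope="session")
def small_random_design():
    """A small random design matrix for clock-fitting unit tests."""
    rng = np.random.default_rng(11)
    ages = np.array([10.0, 12.0, 14.0, 17.0, 19.0, 24.0])
    X = rng.uniform(0, 100, size=(6, 20)).round(2)
    import pandas as pd

    metadata = pd.DataFrame(
        {
            "site_key": [f"MT:{100 + i}:+" for i in range(20)],
            "contig": "MT",
            "position": np.arange(100, 120),
            "strand": "+",
            "mod_type": rng.choice(["5mC", "6mA"], size=20),
            "gene": rng.choice(["ND1", "COX1", "tRNA-Trp"], size=20),
            "mean_coverage": rng.uniform(1, 5, size=20),
            "mean_reliability": rng.uniform(0.8, 1.0, size=20),
        }
    )
    return sites.ClockDesignMatrix(ages=ages, X=X, metadata=metadata)
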