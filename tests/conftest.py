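import sys
from pathlib import Path

import pandas as pd
import pytest

import phytoflux as pf
from phytoflux import pigments, trophic
from phytoflux.tables import RANKS

sys.path.insert(0, str(Path(__file__).parent))


def lineage(division="", class_="", order="", family="", genus="",
            supergroup="", species="", domain="Eukaryota"):
    """Build an eight-rank lineage list with keyword slots."""
    return [domain, supergroup, division, class_, order, family, genus,
            species]


def taxonomy_frame(rows):
    """rows: mapping asv_id -> eight-rank lineage list."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "asv_id"
    return df


def random_counts(rng, n_samples=None, n_asvs=None, density=0.5, max_count=50):
    """A random small ASV table with realistic sparsity."""
    n_samples = n_samples or int(rng.integers(3, 21))
    n_asvs = n_asvs or int(rng.integers(3, 51))
    mat = rng.integers(1, max_count, size=(n_samples, n_asvs))
    mat[rng.random((n_samples, n_asvs)) > density] = 0
    # no empty rows: give each sample one guaranteed count
    for i in range(n_samples):
        if mat[i].sum() == 0:
            mat[i, int(rng.integers(n_asvs))] = 1
    return pd.DataFrame(mat, index=[f"s{i:02d}" for i in range(n_samples)],
                        columns=[f"a{j:03d}" for j in range(n_asvs)])


def random_trap_metadata(rng, sample_ids):
    """Random basin/type/platform metadata over the given samples."""
    rows = {}
    for sid in sample_ids:
        basin = "NP" if rng.random() < 0.5 else "NA"
        stype = ["surface", "bulk_trap", "particle"][int(rng.integers(3))]
        platform = "" if stype == "surface" else f"STT-{int(rng.integers(2))}"
        rows[sid] = {"basin": basin, "sample_type": stype,
                     "depth_m": float(rng.integers(0, 500)),
                     "deployment": int(rng.integers(1, 3)),
                     "platform": platform,
                     "particle_class": "short_pellet" if stype == "particle" else "none",
                     "light_level": ""}
    return pd.DataFrame.from_dict(rows, orient="index")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset with ground truth (seed 0)."""
    return pf.generate_dataset(seed=0)


@pytest.fixture(scope="session")
def classified(default_dataset):
    """The default dataset after trophic + pigment classification and the
    read filter, as the pipeline would see it."""
    ds, gt = default_dataset
    tax = pigments.assign_pigment_groups(trophic.classify_trophic(ds.taxonomy))
    photo = trophic.subset_photosynthetic(ds.counts, tax)
    photo, report = trophic.filter_min_reads(photo)
    return ds, gt, tax, photo
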