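import numpy as np
import pytest

from trunkscope import CallSet, MutationSite, PresenceMatrix, RegionObservation


def make_site(pos, ref="A", alt="T", gene="", func_class="nonsynonymous_snv", chrom="1"):
    return MutationSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, func_class=func_class
    )


def make_obs(region, tumor_depth=100, tumor_alt=30, normal_depth=50, normal_alt=0):
    return RegionObservation(
        region=region,
        tumor_depth=tumor_depth,
        tumor_alt=tumor_alt,
        normal_depth=normal_depth,
        normal_alt=normal_alt,
    )


def matrix_from_rows(rows, regions):
    """rows: dict site -> tuple of 0/1 presence per region."""
    sites = list(rows)
    values = np.array([rows[s] for s in sites], dtype=bool).reshape(
        len(sites), len(regions)
    )
    return PresenceMatrix(sites=sites, regions=list(regions), values=values)


def random_matrix(rng, n_sites, n_regions):
    """Random presence matrix where every site is present somewhere."""
    values = rng.random((n_sites, n_regions)) < rng.uniform(0.2, 0.8)
    for i in range(n_sites):
        if not values[i].any():
            values[i, rng.integers(0, n_regions)] = True
    sites = [make_site(pos=100 + i) for i in range(n_sites)]
    return PresenceMatrix(
        sites=sites, regions=[f"r{j + 1}" for j in range(n_regions)], values=values
    )


@pytest.fixture
def toy_matrix():
    """Three regions; s1 trunk, s2 branch, s3 private."""
    return matrix_from_rows(
        {
            make_site(101): (1, 1, 1),
            make_site(102): (1, 1, 0),
            make_site(103): (1, 0, 0),
        },
        regions=["r1", "r2", "r3"],
    )


@pytest.fixture
def toy_callset():
    """Callset realizing the toy matrix with distinct VAFs per occurrence."""
    sites = {
        101: make_site(101, gene="G1"),
        102: make_site(102, gene="G2"),
        103: make_site(103, gene="G3"),
    }
    presence = {101: ["r1", "r2", "r3"], 102: ["r1", "r2"], 103: ["r1"]}
    records = []
    alt = 10
    for pos, regions in presence.items():
        for r in regions:
            records.append((sites[pos], make_obs(r, tumor_depth=100, tumor_alt=alt)))
            alt += 5
    return CallSet(regions=["r1", "r2", "r3"], records=records)
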