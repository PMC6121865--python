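import numpy as np
import pandas as pd
import pytest

from polypkin.genotype_io import MISSING, GenotypeMatrix
from polypkin.synthetic import ColonyRecipe, PopulationModel, default_recipes, simulate_dataset

FIXTURE_VCF = """\
##fileformat=VCFv4.2
##total_assayed_sites=1000
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##contig=<ID=L1>
##contig=<ID=L2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tp1\tp2\tp3\tp4\tp5
L1\t10\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/0:12\t0/1:15\t1/1:9\t0/1:20\t0/0:8
L1\t40\t.\tC\tG\t.\tPASS\t.\tGT:DP\t./.:3\t0/0:11\t0/0:10\t0/1:13\t1/1:14
L2\t5\t.\tG\tA\t.\tPASS\t.\tGT:DP\t1/1:22\t1/1:18\t0/1:16\t0/0:9\t0/1:12
L2\t61\t.\tT\tC\t.\tPASS\t.\tGT:DP\t0/0:7\t0/0:30\t0/0:25\t0/0:11\t0/1:10
"""

FIXTURE_MAP = """\
sample\tcolony\tlocation\tsex
p1\tCA\tLOC1\tF
p2\tCA\tLOC1\tF
p3\tCA\tLOC1\tF
p4\tCB\tLOC1\tM
p5\tCB\tLOC1\tunknown
"""

# hand transcription of FIXTURE_VCF (samples x sites, MISSING = -1)
FIXTURE_CALLS = np.array(
    [
        [0, MISSING, 2, 0],
        [1, 0, 2, 0],
        [2, 0, 1, 0],
        [1, 1, 0, 0],
        [0, 2, 1, 1],
    ]
)
FIXTURE_DEPTH = np.array(
    [
        [12, 3, 22, 7],
        [15, 11, 18, 30],
        [9, 10, 16, 25],
        [20, 13, 9, 11],
        [8, 14, 12, 10],
    ]
)


@pytest.fixture
def fixture_vcf(tmp_path):
    vcf = tmp_path / "fixture.vcf"
    smap = tmp_path / "samples.tsv"
    vcf.write_text(FIXTURE_VCF)
    smap.write_text(FIXTURE_MAP)
    return vcf, smap


def make_matrix(calls, depth=None, colonies=None, locations=None, total=None, sample_ids=None):
    """Construct a GenotypeMatrix from plain arrays with minimal metadata."""
    calls = np.asarray(calls)
    n, L = calls.shape
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    if depth is None:
        depth = np.full(calls.shape, 30)
    if colonies is None:
        colonies = ["C1"] * n
    if locations is None:
        locations = ["LOC1"] * n
    sm = pd.DataFrame(
        {"sample": sample_ids, "colony": colonies, "location": locations, "sex": "F"}
    ).set_index("sample")
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        site_ids=[f"L{j}:1" for j in range(L)],
        calls=calls,
        depth=depth,
        sample_map=sm,
        total_assayed_sites=total if total is not None else L,
    )


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study at a fixed seed (shared, read-only)."""
    gm, truths, freqs = simulate_dataset(PopulationModel(), default_recipes(), seed=11)
    return gm, truths, freqs


@pytest.fixture(scope="session")
def chimeric_study():
    """Six replicate colonies of the default chimeric recipe (clones +
    brooded sibs + unrelated settlers) at a fixed seed."""
    recipes = [
        ColonyRecipe(colony_id=f"K{i + 1}", location="LOC1" if i < 3 else "LOC2")
        for i in range(6)
    ]
    gm, truths, freqs = simulate_dataset(PopulationModel(), recipes, seed=5)
    return gm, truths, freqs
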