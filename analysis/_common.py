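"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

from polypkin.genotype_io import FilterConfig, read_vcf

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"
SEED = 1

COLONY_FILTER = FilterConfig()  # min depth 8, no missing data, >=100 SNPs


def load_study():
    """Load the simulated study emitted by 01_simulate_colonies.py."""
    gm = read_vcf(DATA / "genotypes.vcf", DATA / "sample_map.tsv")
    truth_pairs = pd.read_csv(DATA / "truth_pairs.tsv", sep="\t")
    truth_labels = pd.read_csv(DATA / "truth_labels.tsv", sep="\t")
    return gm, truth_pairs, truth_labels


def write(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
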