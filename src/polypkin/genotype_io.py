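"""Genotype matrix container, VCF/sample-map I/O and SNP retention filters.

The whole pipeline operates on diploid, biallelic SNP calls for individual
polyps, encoded as alternate-allele dosages (0, 1, 2) with per-call read
depth.  Filtering mirrors the standard RAD-seq colony workflow: mask calls
below a depth floor, keep only sites genotyped in (by default) every polyp
of a colony, and keep only sites still polymorphic within the colony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

SAMPLE_MAP_COLUMNS = ("sample", "colony", "location", "sex")


@dataclass
class FilterConfig:
    """Retention thresholds for colony- and population-level SNP panels.

    Parameters
    ----------
    min_depth:
        Minimum reads supporting a genotype call; calls below it are masked
        to missing before any site-level rule is applied.
    min_presence_fraction:
        Fraction of a group's polyps that must carry a (depth-passing)
        call for the site to be retained.  1.0 means "no missing data".
    min_polyps_per_colony:
        A colony is analyzed only if strictly more than this many polyps
        survive filtering (default 4, i.e. at least 5 polyps retained).
    min_snps_per_colony:
        Minimum number of retained SNPs for a colony to be analyzed.
    one_snp_per_locus:
        Keep at most one SNP per RAD locus (lowest position); used for the
        population-level panels where SNP independence matters.
    """

    min_depth: int = 8
    min_presence_fraction: float = 1.0
    min_polyps_per_colony: int = 4
    min_snps_per_colony: int = 100
    one_snp_per_locus: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0.0 < self.min_presence_fraction <= 1.0:
            raise ValueError("min_presence_fraction must be in (0, 1]")


@dataclass
class GenotypeMatrix:
    """Polyps x sites diploid genotype dosages with depths and metadata.

    ``calls[i, j]`` counts copies of the alternate allele carried by sample
    ``sample_ids[i]`` at site ``site_ids[j]`` (``MISSING`` = no call).
    ``site_ids`` are ``"locus:position"`` strings with 1-based VCF
    positions.  ``total_assayed_sites`` is the number of sites, variant and
    invariant, surveyed to produce the panel; it is the denominator for
    nucleotide diversity and percent-polymorphic statistics.
    """

    sample_ids: list[str]
    site_ids: list[str]
    calls: np.ndarray
    depth: np.ndarray
    sample_map: pd.DataFrame
    total_assayed_sites: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.calls.shape != self.depth.shape:
            raise ValueError("calls and depth must have identical shape")
        if self.calls.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.depth < 0).any():
            raise ValueError("read depths must be non-negative")
        missing = set(self.sample_ids) - set(self.sample_map.index)
        if missing:
            raise ValueError(f"samples absent from sample map: {sorted(missing)}")
        if self.sample_map.index.has_duplicates:
            raise ValueError("duplicate sample in sample map")
        if self.total_assayed_sites < len(self.site_ids):
            raise ValueError("total_assayed_sites < number of sites")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def loci(self) -> np.ndarray:
        """Locus identifier of each site (the part before the last ':')."""
        return np.array([s.rsplit(":", 1)[0] for s in self.site_ids])

    def positions(self) -> np.ndarray:
        return np.array([int(s.rsplit(":", 1)[1]) for s in self.site_ids])

    def colony_of(self, sample_id: str) -> str:
        return str(self.sample_map.loc[sample_id, "colony"])

    def samples_in_colony(self, colony_id: str) -> list[str]:
        mask = self.sample_map.loc[self.sample_ids, "colony"] == colony_id
        return [s for s, m in zip(self.sample_ids, mask) if m]

    def samples_at_location(self, location_id: str) -> list[str]:
        mask = self.sample_map.loc[self.sample_ids, "location"] == location_id
        return [s for s, m in zip(self.sample_ids, mask) if m]

    def colonies(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.colony_of(s), None)
        return list(seen)

    def locations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(str(self.sample_map.loc[s, "location"]), None)
        return list(seen)

    def subset(self, samples=None, sites=None) -> "GenotypeMatrix":
        """Submatrix restricted to the given sample ids / site indices."""
        row_idx = np.arange(self.n_samples)
        col_idx = np.arange(self.n_sites)
        sample_ids = list(self.sample_ids)
        site_ids = list(self.site_ids)
        if samples is not None:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            row_idx = np.array([pos[s] for s in samples], dtype=int)
            sample_ids = list(samples)
        if sites is not None:
            col_idx = np.asarray(sites, dtype=int)
            site_ids = [self.site_ids[j] for j in col_idx]
        return GenotypeMatrix(
            sample_ids=sample_ids,
            site_ids=site_ids,
            calls=self.calls[np.ix_(row_idx, col_idx)],
            depth=self.depth[np.ix_(row_idx, col_idx)],
            sample_map=self.sample_map,
            total_assayed_sites=self.total_assayed_sites,
            meta=dict(self.meta),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.site_ids == other.site_ids
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.depth, other.depth)
            and self.total_assayed_sites == other.total_assayed_sites
        )


def read_sample_map(path) -> pd.DataFrame:
    """Read the 4-column TSV sample map (sample, colony, location, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample map missing columns: {sorted(missing)}")
    bad_sex = set(df["sex"]) - {"M", "F", "unknown"}
    if bad_sex:
        raise ValueError(f"invalid sex values: {sorted(bad_sex)}")
    return df.set_index("sample")


def write_sample_map(sample_map: pd.DataFrame, path) -> None:
    sample_map.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False
    )


def read_vcf(path, sample_map_path, total_assayed_sites: int | None = None) -> GenotypeMatrix:
    """Load a diploid biallelic SNP VCF plus sample map into a GenotypeMatrix.

    Dosage is taken from GT (0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> MISSING),
    depth from the per-sample DP field (0 when absent).  Multiallelic
    records and samples absent from the map are rejected.  If the VCF
    carries a ``##total_assayed_sites=N`` header line it supplies the
    variant+invariant site total unless overridden by the argument.
    """
    sample_map = read_sample_map(sample_map_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = set(samples) - set(sample_map.index)
    if unknown:
        raise ValueError(f"VCF samples missing from sample map: {sorted(unknown)}")

    header_total = None
    for line in vcf.raw_header.splitlines():
        if line.startswith("##total_assayed_sites="):
            header_total = int(line.split("=", 1)[1])

    site_ids: list[str] = []
    calls_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        site_ids.append(f"{rec.CHROM}:{rec.POS}")
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        dosage = np.array(
            [a0 + a1 if a0 >= 0 and a1 >= 0 else MISSING for a0, a1, *_ in gts],
            dtype=np.int16,
        )
        dp = rec.format("DP")
        if dp is None:
            depth = np.zeros(len(samples), dtype=np.int32)
        else:
            depth = np.asarray(dp, dtype=np.int32).reshape(-1)
            depth[depth < 0] = 0
        calls_rows.append(dosage)
        depth_rows.append(depth)

    n_sites = len(site_ids)
    calls = (
        np.stack(calls_rows, axis=1) if n_sites else np.zeros((len(samples), 0), np.int16)
    )
    depth = (
        np.stack(depth_rows, axis=1) if n_sites else np.zeros((len(samples), 0), np.int32)
    )
    total = total_assayed_sites if total_assayed_sites is not None else header_total
    return GenotypeMatrix(
        sample_ids=samples,
        site_ids=site_ids,
        calls=calls,
        depth=depth,
        sample_map=sample_map,
        total_assayed_sites=total if total is not None else n_sites,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCFv4.2 file (GT:DP, REF=A, ALT=T).

    The synthetic pipeline does not model nucleotide identity, so fixed
    placeholder alleles are written; ``read_vcf`` round-trips calls,
    depths, site ids and sample order bit-exactly.
    """
    path = Path(path)
    loci = gm.loci()
    positions = gm.positions()
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##total_assayed_sites={gm.total_assayed_sites}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for locus in dict.fromkeys(loci):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            fields = [
                str(loci[j]),
                str(positions[j]),
                ".",
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for i in range(gm.n_samples):
                fields.append(f"{_GT_STRINGS[int(gm.calls[i, j])]}:{int(gm.depth[i, j])}")
            fh.write("\t".join(fields) + "\n")


def _site_is_polymorphic(column: np.ndarray) -> bool:
    """Both alleles observed among the non-missing calls (allele-wise:
    a site where every call is heterozygous is polymorphic)."""
    observed = column[column != MISSING]
    if observed.size == 0:
        return False
    return bool((observed == 1).any() or ((observed == 0).any() and (observed == 2).any()))


def _apply_site_rules(
    calls: np.ndarray, depth: np.ndarray, cfg: FilterConfig
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Mask low-depth calls, then apply presence and polymorphism rules.

    Returns the masked calls, a boolean keep-mask over sites and a report
    of sites dropped per rule.
    """
    masked = calls.copy()
    low = depth < cfg.min_depth
    masked[low] = MISSING
    n_samples = calls.shape[0]

    present = (masked != MISSING).sum(axis=0)
    presence_ok = present >= cfg.min_presence_fraction * n_samples - 1e-9
    poly_ok = np.array([_site_is_polymorphic(masked[:, j]) for j in range(calls.shape[1])])

    keep = presence_ok & poly_ok
    report = {
        "n_calls_masked_low_depth": int(low.sum()),
        "n_sites_dropped_presence": int((~presence_ok).sum()),
        "n_sites_dropped_monomorphic": int((presence_ok & ~poly_ok).sum()),
        "n_sites_retained": int(keep.sum()),
    }
    return masked, keep, report


def filter_colony_panel(
    gm: GenotypeMatrix, colony_id: str, cfg: FilterConfig
) -> GenotypeMatrix:
    """Colony-level retention: depth mask, presence fraction, polymorphism.

    Calls supported by fewer than ``cfg.min_depth`` reads are set to
    missing first; a site is then retained only if genotyped in at least
    ``min_presence_fraction`` of the colony's polyps and still polymorphic
    within the colony.  Per-rule drop counts are recorded in
    ``panel.meta["filter_report"]``.  An empty result is returned with
    ``meta["empty_warning"]`` set rather than raised.
    """
    samples = gm.samples_in_colony(colony_id)
    if not samples:
        raise ValueError(f"unknown colony: {colony_id}")
    sub = gm.subset(samples=samples)
    masked, keep, report = _apply_site_rules(sub.calls, sub.depth, cfg)
    keep_idx = np.flatnonzero(keep)
    panel = GenotypeMatrix(
        sample_ids=sub.sample_ids,
        site_ids=[sub.site_ids[j] for j in keep_idx],
        calls=masked[:, keep_idx],
        depth=sub.depth[:, keep_idx],
        sample_map=gm.sample_map,
        total_assayed_sites=gm.total_assayed_sites,
        meta={"colony_id": colony_id, "filter_report": report},
    )
    if panel.n_sites == 0:
        panel.meta["empty_warning"] = True
        warnings.warn(f"colony {colony_id}: no sites survive filtering", stacklevel=2)
    return panel


def colony_passes_retention(panel: GenotypeMatrix, cfg: FilterConfig) -> tuple[bool, str | None]:
    """Colony analyzed iff polyps > min_polyps_per_colony and SNPs >= min_snps."""
    if panel.n_samples <= cfg.min_polyps_per_colony:
        return False, "polyp count"
    if panel.n_sites < cfg.min_snps_per_colony:
        return False, "snp count"
    return True, None


def population_panel(gm: GenotypeMatrix, location_id: str, cfg: FilterConfig) -> GenotypeMatrix:
    """Location-level panel with relaxed presence, optionally one SNP/locus.

    With ``cfg.one_snp_per_locus`` the panel keeps, per RAD locus, the
    lowest-position SNP (deterministic stand-in for the assembler's
    write-single-SNP behavior) — used where SNP independence matters
    (relatedness estimation).  Diversity statistics may keep all SNPs.
    """
    samples = gm.samples_at_location(location_id)
    if not samples:
        return GenotypeMatrix(
            sample_ids=[],
            site_ids=[],
            calls=np.zeros((0, 0), np.int16),
            depth=np.zeros((0, 0), np.int32),
            sample_map=gm.sample_map,
            total_assayed_sites=gm.total_assayed_sites,
            meta={"location_id": location_id, "empty_warning": True},
        )
    sub = gm.subset(samples=samples)
    masked, keep, report = _apply_site_rules(sub.calls, sub.depth, cfg)
    keep_idx = np.flatnonzero(keep)

    loci = sub.loci()
    positions = sub.positions()
    if cfg.one_snp_per_locus:
        # lowest position per locus wins, ties broken by site id
        best: dict[str, int] = {}
        for j in keep_idx:
            locus = loci[j]
            if locus not in best:
                best[locus] = j
            else:
                k = best[locus]
                if (positions[j], sub.site_ids[j]) < (positions[k], sub.site_ids[k]):
                    best[locus] = j
        chosen = sorted(best.values(), key=lambda j: (loci[j], positions[j]))
    else:
        chosen = list(keep_idx)
    report["n_sites_dropped_locus_dedup"] = int(len(keep_idx) - len(chosen))
    return GenotypeMatrix(
        sample_ids=sub.sample_ids,
        site_ids=[sub.site_ids[j] for j in chosen],
        calls=masked[:, chosen],
        depth=sub.depth[:, chosen],
        sample_map=gm.sample_map,
        total_assayed_sites=gm.total_assayed_sites,
        meta={"location_id": location_id, "filter_report": report},
    )
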