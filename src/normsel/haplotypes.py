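"""Individual SNP genotypes -> region-wide haplotype (RWH) count tables.

Individuals of a fully selfing population are genotyped at biallelic SNPs on
one two-chromosome genomic *region* each (chromosomes I+II = region 1,
III+IV = region 2, V+X = region 3). Because individuals are essentially
homozygous, the ordered allele string over the retained SNPs of a chromosome
defines a chromosome-wide haplotype (CWH), and the concatenation of a region's
two CWHs defines the individual's region-wide haplotype (RWH).

This module reads genotype tables, applies quality control, constructs
CWHs/RWHs, tallies RWH counts per population/epoch/region, groups
minor-frequency RWHs into a per-region background class, and pools replicate
populations to the regime level for likelihood-based inference.

Genotype tables are tab-separated with columns
``population, generation, individual, region, chromosome, snp_id, position,
call`` and call codes ``REF, ALT, HET, MISSING``. Population identifiers are
``<regime>_<replicate>`` (e.g. ``sudden_1``, ``ancestral_0``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOME_REGION",
    "REGION_CHROMOSOMES",
    "BACKGROUND_IDS",
    "QcReport",
    "GroupedRwhTable",
    "GenotypeObservations",
    "read_genotype_table",
    "apply_qc",
    "calls_to_cwh",
    "cwh_to_rwh",
    "tally_rwh",
    "group_minor",
    "pool_to_regime",
    "read_rwh_counts",
    "write_rwh_counts",
]

#: C. elegans chromosome -> genotyping region.
CHROMOSOME_REGION: dict[str, int] = {"I": 1, "II": 1, "III": 2, "IV": 2, "V": 3, "X": 3}
REGION_CHROMOSOMES: dict[int, tuple[str, str]] = {1: ("I", "II"), 2: ("III", "IV"), 3: ("V", "X")}
#: Synthetic background pseudo-RWH id per region (aggregate of minor RWHs).
BACKGROUND_IDS: dict[int, str] = {1: "H0A", 2: "H0B", 3: "H0C"}

CALL_CODES = frozenset({"REF", "ALT", "HET", "MISSING"})
GENOTYPE_COLUMNS = [
    "population",
    "generation",
    "individual",
    "region",
    "chromosome",
    "snp_id",
    "position",
    "call",
]

_INDIV_KEY = ["population", "generation", "individual"]


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a genotype TSV into a calls DataFrame.

    Every row is one SNP call for one individual. Malformed rows raise with
    the offending row index and column; nothing is skipped silently.
    """
    df = pd.read_csv(path, sep="\t", dtype={"population": str, "individual": str,
                                            "chromosome": str, "snp_id": str, "call": str})
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype table {path} missing required columns {missing_cols}")
    bad_call = ~df["call"].isin(CALL_CODES)
    if bad_call.any():
        i = int(df.index[bad_call][0])
        raise ValueError(
            f"row {i}: unknown call code {df.loc[i, 'call']!r} (column 'call')"
        )
    bad_chrom = ~df["chromosome"].isin(CHROMOSOME_REGION)
    if bad_chrom.any():
        i = int(df.index[bad_chrom][0])
        raise ValueError(f"row {i}: unknown chromosome {df.loc[i, 'chromosome']!r}")
    expected_region = df["chromosome"].map(CHROMOSOME_REGION)
    mismatch = expected_region != df["region"]
    if mismatch.any():
        i = int(df.index[mismatch][0])
        raise ValueError(
            f"row {i}: chromosome {df.loc[i, 'chromosome']!r} inconsistent with "
            f"region {df.loc[i, 'region']} (column 'region')"
        )
    n_regions = df.groupby(_INDIV_KEY)["region"].nunique()
    if (n_regions > 1).any():
        who = n_regions[n_regions > 1].index[0]
        raise ValueError(f"individual {who} genotyped in more than one region")
    df["generation"] = df["generation"].astype(int)
    df["position"] = df["position"].astype(int)
    return df.reset_index(drop=True)


@dataclass
class QcReport:
    """Outcome of genotype quality control."""

    dropped_snps: list[str]
    dropped_individuals: list[tuple]
    snp_fail_threshold: float
    individual_fail_threshold: float
    het_threshold: float
    n_passes: int = 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dropped_snps": sorted(self.dropped_snps),
            "dropped_individuals": [list(k) for k in sorted(self.dropped_individuals)],
            "thresholds": {
                "snp_fail_threshold": self.snp_fail_threshold,
                "individual_fail_threshold": self.individual_fail_threshold,
                "het_threshold": self.het_threshold,
            },
            "n_passes": self.n_passes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def apply_qc(
    calls: pd.DataFrame,
    snp_fail_threshold: float = 0.30,
    individual_fail_threshold: float = 0.25,
    het_threshold: float = 0.30,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop low-quality SNPs and individuals.

    SNPs with a MISSING fraction above ``snp_fail_threshold`` or a HET fraction
    above ``het_threshold`` (fractions over the individuals assayed for them)
    are dropped first, then individuals whose fraction of MISSING calls among
    retained SNPs exceeds ``individual_fail_threshold``. The two filters are
    re-applied until stable so the thresholds hold jointly on the output,
    which also makes the operation idempotent.
    """
    for name, thr in (
        ("snp_fail_threshold", snp_fail_threshold),
        ("individual_fail_threshold", individual_fail_threshold),
        ("het_threshold", het_threshold),
    ):
        if not (0 < thr <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {thr}")

    kept = calls
    dropped_snps: list[str] = []
    dropped_individuals: list[tuple] = []
    n_passes = 0
    while True:
        n_passes += 1
        frac = kept.groupby("snp_id")["call"].agg(
            missing=lambda s: (s == "MISSING").mean(),
            het=lambda s: (s == "HET").mean(),
        )
        bad_snps = frac.index[
            (frac["missing"] > snp_fail_threshold) | (frac["het"] > het_threshold)
        ]
        if len(bad_snps):
            dropped_snps.extend(bad_snps)
            kept = kept[~kept["snp_id"].isin(set(bad_snps))]
        if kept.empty:
            raise ValueError("QC removed all SNPs")
        ind_fail = kept.groupby(_INDIV_KEY)["call"].agg(lambda s: (s == "MISSING").mean())
        bad_inds = ind_fail.index[ind_fail > individual_fail_threshold]
        if len(bad_inds):
            dropped_individuals.extend(bad_inds)
            idx = pd.MultiIndex.from_frame(kept[_INDIV_KEY])
            kept = kept[~idx.isin(bad_inds)]
        if kept.empty:
            raise ValueError("QC removed all individuals")
        if not len(bad_snps) and not len(bad_inds):
            break
    report = QcReport(
        dropped_snps=list(dict.fromkeys(dropped_snps)),
        dropped_individuals=list(dict.fromkeys(dropped_individuals)),
        snp_fail_threshold=snp_fail_threshold,
        individual_fail_threshold=individual_fail_threshold,
        het_threshold=het_threshold,
        n_passes=n_passes,
    )
    return kept.reset_index(drop=True), report


def calls_to_cwh(calls: pd.DataFrame, max_impute: int = 1) -> pd.DataFrame:
    """Build per-individual chromosome-wide haplotypes from homozygous calls.

    Selfing individuals are expected to be homozygous: any HET call at a
    retained SNP excludes the individual from haplotype construction (external
    phasing is out of scope). Up to ``max_impute`` MISSING calls per chromosome
    are imputed to the major allele among same-sample individuals; more than
    that excludes the individual. Returns one row per (individual, chromosome)
    with an ``allele_string`` over {0, 1} ordered by position.
    """
    # major allele per (population, generation, snp) for single-site imputation
    hom = calls[calls["call"].isin(("REF", "ALT"))]
    alt_share = hom.groupby(["population", "generation", "snp_id"])["call"].agg(
        lambda s: (s == "ALT").mean()
    )
    major = (alt_share > 0.5).map({True: "1", False: "0"})

    rows = []
    excluded = 0
    for (pop, gen, ind), grp in calls.groupby(_INDIV_KEY, sort=False):
        if (grp["call"] == "HET").any():
            excluded += 1
            continue
        ok = True
        chrom_strings = {}
        for chrom, sub in grp.groupby("chromosome", sort=False):
            sub = sub.sort_values("position")
            alleles = []
            n_missing = 0
            for snp_id, call in zip(sub["snp_id"], sub["call"]):
                if call == "MISSING":
                    n_missing += 1
                    if n_missing > max_impute:
                        ok = False
                        break
                    alleles.append(major.get((pop, gen, snp_id), "0"))
                else:
                    alleles.append("1" if call == "ALT" else "0")
            if not ok:
                break
            chrom_strings[chrom] = "".join(alleles)
        if not ok:
            excluded += 1
            continue
        region = int(grp["region"].iloc[0])
        for chrom, s in chrom_strings.items():
            rows.append((pop, int(gen), ind, region, chrom, s))
    if excluded:
        warnings.warn(
            f"{excluded} individual(s) excluded from haplotype construction "
            "(residual HET or excess MISSING calls)",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["population", "generation", "individual", "region", "chromosome", "allele_string"],
    )


def cwh_to_rwh(cwhs: pd.DataFrame) -> pd.DataFrame:
    """Concatenate each individual's two CWHs into its region-wide haplotype.

    The RWH identifier is the concatenation of the two allele strings in
    canonical chromosome order, prefixed by the region, so identical genotypes
    map to identical ids. Individuals with only one chromosome genotyped are
    excluded with a warning.
    """
    rows = []
    excluded = 0
    for (pop, gen, ind), grp in cwhs.groupby(_INDIV_KEY, sort=False):
        region = int(grp["region"].iloc[0])
        expected = REGION_CHROMOSOMES[region]
        by_chrom = dict(zip(grp["chromosome"], grp["allele_string"]))
        if set(by_chrom) != set(expected):
            excluded += 1
            continue
        rwh_id = f"R{region}:{by_chrom[expected[0]]}{by_chrom[expected[1]]}"
        rows.append((pop, int(gen), ind, region, rwh_id))
    if excluded:
        warnings.warn(
            f"{excluded} individual(s) excluded (only one chromosome genotyped)",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["population", "generation", "individual", "region", "rwh_id"])


def _split_population(pop: str) -> tuple[str, str]:
    regime, _, replicate = pop.rpartition("_")
    if not regime:
        return pop, "0"
    return regime, replicate


def tally_rwh(rwhs: pd.DataFrame) -> pd.DataFrame:
    """Tally RWH copies per (regime, replicate, generation, region).

    Population ids of the form ``<regime>_<replicate>`` are split into the
    regime and replicate columns of the output count table.
    """
    df = rwhs.copy()
    regime_rep = df["population"].map(_split_population)
    df["regime"] = regime_rep.map(lambda t: t[0])
    df["replicate"] = regime_rep.map(lambda t: t[1])
    counts = (
        df.groupby(["regime", "replicate", "generation", "region", "rwh_id"])
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


def write_rwh_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_rwh_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"regime": str, "replicate": str, "rwh_id": str})
    required = {"regime", "replicate", "generation", "region", "rwh_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns {sorted(missing)}")
    return df


@dataclass
class GroupedRwhTable:
    """RWH counts with minor haplotypes collapsed into background classes.

    ``table`` has minor RWHs replaced by their region's background pseudo-RWH
    (H0A/H0B/H0C) with counts summed; ``primary`` maps
    (regime, replicate, region) to the replicate's primary RWH ids; ``raw``
    keeps the ungrouped counts so regime-level pooling can re-group under the
    union of primaries.
    """

    table: pd.DataFrame
    primary: dict[tuple[str, str, int], tuple[str, ...]]
    raw: pd.DataFrame


def _max_observed_frequency(counts: pd.DataFrame) -> pd.DataFrame:
    """Per (regime, replicate, region, rwh): max frequency across epochs, total count."""
    df = counts.copy()
    totals = df.groupby(["regime", "replicate", "generation", "region"])["count"].transform("sum")
    df["freq"] = df["count"] / totals
    agg = (
        df.groupby(["regime", "replicate", "region", "rwh_id"])
        .agg(max_freq=("freq", "max"), total=("count", "sum"))
        .reset_index()
    )
    return agg


def group_minor(counts: pd.DataFrame, top_k: int = 3) -> GroupedRwhTable:
    """Designate each replicate's top RWHs as primary; pool the rest.

    RWHs are ranked within each replicate population and region by the maximum
    frequency they reach across that replicate's genotyped generations (ties
    broken by total count, then lexicographic id). The top ``top_k`` are
    primary; all others are summed into a single background pseudo-RWH per
    region. Total counts are conserved exactly.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    agg = _max_observed_frequency(counts)
    primary: dict[tuple[str, str, int], tuple[str, ...]] = {}
    for (regime, rep, region), grp in agg.groupby(["regime", "replicate", "region"]):
        ranked = grp.sort_values(
            by=["max_freq", "total", "rwh_id"], ascending=[False, False, True]
        )
        primary[(regime, rep, int(region))] = tuple(ranked["rwh_id"].head(top_k))

    df = counts.copy()
    is_primary = [
        row.rwh_id in primary[(row.regime, row.replicate, int(row.region))]
        for row in df.itertuples()
    ]
    df["designation"] = np.where(is_primary, "primary", "background")
    df.loc[df["designation"] == "background", "rwh_id"] = df.loc[
        df["designation"] == "background", "region"
    ].map(BACKGROUND_IDS)
    grouped = (
        df.groupby(
            ["regime", "replicate", "generation", "region", "rwh_id", "designation"],
            as_index=False,
        )["count"]
        .sum()
    )
    return GroupedRwhTable(table=grouped, primary=primary, raw=counts.copy())


@dataclass
class GenotypeObservations:
    """Regime-level RWH counts per epoch and region, ready for the likelihood.

    ``table`` columns: regime, generation, region, rwh_id, count, designation.
    ``rwh_region`` maps every RWH id (including background pseudo-RWHs) to its
    region; ``primary`` maps (regime, region) to the regime-wide primary set
    (union over replicates).
    """

    table: pd.DataFrame
    rwh_region: dict[str, int]
    primary: dict[tuple[str, int], tuple[str, ...]]

    def regimes(self) -> list[str]:
        return sorted(self.table["regime"].unique())

    def epochs(self, regime: str) -> list[int]:
        sub = self.table[self.table["regime"] == regime]
        return sorted(sub["generation"].unique())

    def counts_at(self, regime: str, generation: int) -> dict[str, int]:
        sub = self.table[
            (self.table["regime"] == regime) & (self.table["generation"] == generation)
        ]
        return dict(zip(sub["rwh_id"], sub["count"].astype(int)))

    def region_counts_at(self, regime: str, generation: int) -> dict[int, dict[str, int]]:
        out: dict[int, dict[str, int]] = {}
        sub = self.table[
            (self.table["regime"] == regime) & (self.table["generation"] == generation)
        ]
        for region, grp in sub.groupby("region"):
            out[int(region)] = dict(zip(grp["rwh_id"], grp["count"].astype(int)))
        return out


def pool_to_regime(grouped: GroupedRwhTable) -> GenotypeObservations:
    """Pool replicate counts to the regime level.

    Replicates within a regime are modeled as draws from the same lineage
    frequencies, so their counts simply add. The regime-wide primary set is
    the union of the replicate primary sets: an RWH grouped into the
    background in one replicate but primary in another stays primary
    regime-wide (re-grouped from the raw counts).
    """
    union: dict[tuple[str, int], set[str]] = {}
    for (regime, _rep, region), ids in grouped.primary.items():
        union.setdefault((regime, region), set()).update(ids)
    primary = {k: tuple(sorted(v)) for k, v in union.items()}

    df = grouped.raw.copy()
    is_primary = [
        row.rwh_id in union.get((row.regime, int(row.region)), set())
        for row in df.itertuples()
    ]
    df["designation"] = np.where(is_primary, "primary", "background")
    df.loc[df["designation"] == "background", "rwh_id"] = df.loc[
        df["designation"] == "background", "region"
    ].map(BACKGROUND_IDS)
    pooled = (
        df.groupby(["regime", "generation", "region", "rwh_id", "designation"], as_index=False)[
            "count"
        ].sum()
    )
    rwh_region = dict(zip(pooled["rwh_id"], pooled["region"].astype(int)))
    for region, bg in BACKGROUND_IDS.items():
        rwh_region.setdefault(bg, region)
    return GenotypeObservations(table=pooled, rwh_region=rwh_region, primary=primary)
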