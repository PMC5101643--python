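"""Population-scale statistics for the CNV locus.

Covers the sequence-panel side of the analysis: filtering a bi-allelic
SNP matrix (MAF and missingness thresholds), pairwise distances with a
Nexus export for phylogenetic-network tools, LD R² between SNPs and
between SNPs and CNV genotype (one-vs-rest per pattern), the
missingness-based deletion classifier for N-masked pseudogenomes, and
genotype frequency tables.

Accessions are inbred and homozygous, so SNP genotypes are treated as
haploid indicators throughout; on complete data the squared Pearson
correlation used here coincides with the classical haplotype
``D²/(p_A p_a p_B p_b)`` measure of LD.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from athcnv.locus import GenomicInterval

__all__ = [
    "filter_snps",
    "pairwise_distance",
    "write_nexus",
    "ld_r2",
    "snp_indicator",
    "cnv_ld_scan",
    "missingness_fraction",
    "predict_del2",
    "genotype_frequencies",
]

MISSING = "N"


def _site_stats(row: np.ndarray, subset_mask: np.ndarray | None = None):
    vals = row if subset_mask is None else row[subset_mask]
    called = vals[vals != MISSING]
    missing_frac = 1.0 - len(called) / len(vals) if len(vals) else 1.0
    if len(called) == 0:
        return missing_frac, 0.0, []
    alleles, counts = np.unique(called, return_counts=True)
    maf = counts.min() / counts.sum() if len(alleles) >= 2 else 0.0
    return missing_frac, maf, list(alleles)


def filter_snps(
    matrix: pd.DataFrame,
    panel_subset: Sequence[str] | None = None,
    min_maf: float = 0.10,
    max_missing: float = 0.20,
    require_biallelic: bool = True,
) -> pd.DataFrame:
    """Retain informative SNP positions.

    Keeps sites that are bi-allelic across the full panel, reach
    ``min_maf`` minor-allele frequency within ``panel_subset`` (over
    non-missing calls) and have a missing fraction strictly below
    ``max_missing`` within the subset.  Row order is preserved.
    """
    if panel_subset is None:
        panel_subset = list(matrix.columns)
    if len(panel_subset) == 0:
        raise ValueError("panel subset must be non-empty")
    missing_cols = set(panel_subset) - set(matrix.columns)
    if missing_cols:
        raise ValueError(f"subset accessions absent: {sorted(missing_cols)}")
    subset_mask = matrix.columns.isin(panel_subset)

    keep = []
    values = matrix.to_numpy()
    for i in range(len(matrix)):
        row = values[i]
        if require_biallelic:
            called = row[row != MISSING]
            if len(np.unique(called)) != 2:
                continue
        missing_frac, maf, _ = _site_stats(row, subset_mask)
        if missing_frac >= max_missing:
            continue
        if maf < min_maf:
            continue
        keep.append(i)
    out = matrix.iloc[keep]
    if out.empty:
        warnings.warn("no SNPs survive filtering", stacklevel=2)
    return out


def pairwise_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Proportion-of-differences distance between accessions.

    ``d(i, j)`` is the fraction of positions called in both accessions
    where the alleles differ; pairs with zero co-called sites get NaN.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two accessions")
    acc = list(matrix.columns)
    vals = matrix.to_numpy()
    called = vals != MISSING
    n = len(acc)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = both.sum()
            if m == 0:
                d = np.nan
            else:
                d = float(np.mean(vals[both, i] != vals[both, j]))
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=acc, columns=acc)


def write_nexus(
    matrix: pd.DataFrame,
    distances: pd.DataFrame | None = None,
    path=None,
) -> str:
    """Nexus file with the concatenated SNP alignment and distance matrix.

    Emits a TAXA block, a CHARACTERS block (datatype=dna, missing=N) with
    the concatenated per-accession SNP pseudo-alignment, and a DISTANCES
    block — the input format network tools such as SplitsTree consume.
    """
    if distances is None:
        distances = pairwise_distance(matrix)
    acc = list(matrix.columns)
    nchar = len(matrix)
    lines = ["#NEXUS", ""]
    lines += [
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={len(acc)};",
        "  TAXLABELS",
        *[f"    '{a}'" for a in acc],
        "  ;",
        "END;",
        "",
        "BEGIN CHARACTERS;",
        f"  DIMENSIONS NCHAR={nchar};",
        "  FORMAT DATATYPE=DNA MISSING=N GAP=-;",
        "  MATRIX",
    ]
    for a in acc:
        seq = "".join(matrix[a].tolist())
        lines.append(f"    '{a}' {seq}")
    lines += ["  ;", "END;", "", "BEGIN DISTANCES;",
              f"  DIMENSIONS NTAX={len(acc)};",
              "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
              "  MATRIX"]
    for a in acc:
        row = " ".join(
            "?" if np.isnan(distances.loc[a, b]) else f"{distances.loc[a, b]:.6f}"
            for b in acc
        )
        lines.append(f"    '{a}' {row}")
    lines += ["  ;", "END;", ""]
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def snp_indicator(row: pd.Series | np.ndarray) -> np.ndarray:
    """Haploid 0/1 indicator of the minor allele; NaN where missing."""
    vals = np.asarray(row)
    out = np.full(len(vals), np.nan)
    called = vals != MISSING
    alleles, counts = np.unique(vals[called], return_counts=True)
    if len(alleles) == 0:
        return out
    minor = alleles[np.argmin(counts)]
    out[called] = (vals[called] == minor).astype(float)
    return out


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two binary indicator vectors.

    Computed over entries non-missing (non-NaN) in both; constant vectors
    make R² undefined (NaN).  Sign-invariant: complementing either vector
    leaves the value unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        return float("nan")
    xv, yv = x[mask], y[mask]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return float("nan")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def cnv_ld_scan(
    matrix: pd.DataFrame,
    panel: pd.DataFrame,
    patterns: Iterable[str] | None = None,
) -> pd.DataFrame:
    """R² between every SNP and every CNV pattern (one-vs-rest).

    ``panel`` must map accession (index) to a ``genotype_pattern``
    column.  Returns one row per SNP with per-pattern R² and their
    maximum; patterns absent from the panel are skipped.
    """
    acc = [a for a in matrix.columns if a in panel.index]
    if not acc:
        raise ValueError("no accessions shared between matrix and panel")
    sub = matrix[acc]
    pat_series = panel.loc[acc, "genotype_pattern"]
    if patterns is None:
        patterns = sorted(pat_series.unique())
    indicators = {
        p: (pat_series == p).to_numpy(dtype=float) for p in patterns
    }
    rows = []
    for pos in sub.index:
        x = snp_indicator(sub.loc[pos])
        row = {"position": pos}
        for p, y in indicators.items():
            row[p] = ld_r2(x, y)
        vals = [v for k, v in row.items() if k != "position"]
        row["max_r2"] = np.nanmax(vals) if not np.all(np.isnan(vals)) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


def missingness_fraction(
    pseudogenome: str,
    region: GenomicInterval,
    seq_region: GenomicInterval,
) -> float:
    """Fraction of N characters over a genomic region of a pseudogenome.

    ``seq_region`` states which genomic span the sequence string covers
    (the string's first base is ``seq_region.start``).
    """
    if len(pseudogenome) != seq_region.length:
        raise ValueError("sequence length does not match its declared region")
    if not seq_region.contains(region):
        raise ValueError(f"region {region} outside sequence bounds")
    lo = region.start - seq_region.start
    hi = region.end - seq_region.start + 1
    window = pseudogenome[lo:hi]
    return window.upper().count(MISSING) / len(window)


def predict_del2(fraction: float, threshold: float = 0.80) -> bool:
    """Deletion call from local missingness: true iff ``fraction >= 0.80``.

    Short-read genotyping leaves a homozygously deleted region essentially
    uncalled, so a pseudogenome with at least 80% N over the deletable
    block is classified as carrying the deletion.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be within [0, 1]")
    return fraction >= threshold


def genotype_frequencies(
    panel: pd.DataFrame,
    grouping: str = "none",
    decimals: int = 2,
) -> pd.DataFrame:
    """Frequency table of CNV patterns, optionally per country group.

    Returns one row per group plus an ``All`` row with the accession
    count and, per pattern, the count and percentage (rounded to
    ``decimals``; percentages are stored as numbers and formatted only at
    the report layer).
    """
    if "genotype_pattern" not in panel.columns:
        raise ValueError("panel must have a genotype_pattern column")
    if grouping == "none":
        groups = {"All": panel}
    elif grouping in panel.columns:
        groups = {k: v for k, v in panel.groupby(grouping)}
        groups["All"] = panel
    else:
        raise ValueError(f"unknown grouping key {grouping!r}")
    canonical = ["basic", "del-2", "dupl-1", "dupl-2", "dupl-3-a", "dupl-3-b"]
    extras = sorted(set(panel["genotype_pattern"].unique()) - set(canonical))
    patterns = canonical + extras
    rows = []
    for name, sub in groups.items():
        n = len(sub)
        row = {"group": name, "n": n}
        counts = sub["genotype_pattern"].value_counts()
        for p in patterns:
            c = int(counts.get(p, 0))
            row[f"{p}_n"] = c
            row[f"{p}_pct"] = round(100.0 * c / n, decimals) if n else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group")
    # stable ordering: groups alphabetically, All last
    order = sorted(g for g in out.index if g != "All") + ["All"]
    return out.loc[order]
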