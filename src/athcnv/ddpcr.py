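"""Droplet digital PCR quantification and MLPA concordance.

A ddPCR well partitions the template over ~18,000 droplets; with mean
occupancy λ copies/droplet the fraction of positive droplets is
``1 − e^(−λ)``, so ``λ = −ln(1 − positives/total)``.  Copy numbers are
background-corrected against the no-template control and normalized
within-sample to the DCL1 reference gene (defined diploid copy number 2).
Replicate wells are merged by pooling droplet counts before estimation,
which preserves the Poisson likelihood.

``DdpcrAssay(wells).fit()`` returns a :class:`DdpcrResults` with one
copy-number estimate (and Poisson 95% interval) per sample × gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SaturatedWellError",
    "poisson_lambda",
    "lambda_variance",
    "background_correct",
    "copy_number",
    "CopyNumberEstimate",
    "DdpcrAssay",
    "DdpcrResults",
    "concordance",
    "trichotomize_cn",
]


class SaturatedWellError(ValueError):
    """All droplets positive: λ is unbounded; dilute the template."""


def poisson_lambda(positive: int, total: int) -> float:
    """Mean copies per droplet from a droplet count pair.

    ``λ = −ln(1 − positive/total)``; 0 positives give exactly 0.  A fully
    positive well leaves λ undefined and raises
    :class:`SaturatedWellError`.
    """
    if total < 1:
        raise ValueError("total droplets must be >= 1")
    if positive < 0 or positive > total:
        raise ValueError(
            f"positive droplets ({positive}) outside [0, {total}]"
        )
    if positive == total:
        raise SaturatedWellError(
            f"all {total} droplets positive; copy number unbounded"
        )
    if positive == 0:
        return 0.0
    return -math.log1p(-positive / total)


def lambda_variance(lam: float, total: int) -> float:
    """Counting-error variance of the λ estimate: ``(e^λ − 1)/N``."""
    return math.expm1(lam) / total


def background_correct(lambda_sample: float, lambda_ntc: float) -> float:
    """Subtract the no-template-control rate, clamping at zero."""
    if lambda_sample < 0 or lambda_ntc < 0:
        raise ValueError("rates must be non-negative")
    return max(lambda_sample - lambda_ntc, 0.0)


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Per-sample, per-gene diploid copy number with Poisson 95% CI."""

    sample: str
    gene: str
    lambda_target: float
    lambda_ref: float
    cn_float: float
    cn_int: int
    ci_low: float
    ci_high: float


def copy_number(
    lambda_target: float,
    lambda_reference: float,
    reference_cn: int = 2,
    target_droplets: int | None = None,
    reference_droplets: int | None = None,
    sample: str = "",
    gene: str = "",
) -> CopyNumberEstimate:
    """Diploid copy number of a target relative to the reference gene.

    ``cn = reference_cn · λ_target / λ_reference``; the 95% interval
    propagates the Poisson counting error of both λ estimates when the
    droplet totals are supplied (delta method on the ratio).  ddPCR
    resolves single-copy steps, so ``cn_int`` rounds to the nearest
    integer, not the nearest even one.
    """
    if lambda_reference <= 0:
        raise ValueError("reference assay failed (lambda_reference <= 0)")
    if lambda_target < 0:
        raise ValueError("lambda_target must be >= 0")
    cn = reference_cn * lambda_target / lambda_reference
    ci_low = ci_high = float("nan")
    if target_droplets and reference_droplets and lambda_target > 0:
        rel_var = (
            lambda_variance(lambda_target, target_droplets) / lambda_target**2
            + lambda_variance(lambda_reference, reference_droplets)
            / lambda_reference**2
        )
        se = cn * math.sqrt(rel_var)
        z = stats.norm.ppf(0.975)
        ci_low = max(cn - z * se, 0.0)
        ci_high = cn + z * se
    elif lambda_target == 0:
        ci_low = ci_high = 0.0
    return CopyNumberEstimate(
        sample=sample,
        gene=gene,
        lambda_target=lambda_target,
        lambda_ref=lambda_reference,
        cn_float=cn,
        cn_int=max(int(round(cn)), 0),
        ci_low=ci_low,
        ci_high=ci_high,
    )


@dataclass
class DdpcrResults:
    """Fitted ddPCR panel: one copy-number row per sample × gene."""

    estimates: pd.DataFrame
    reference_assay: str
    lambda_ntc: dict

    def summary(self) -> str:
        df = self.estimates
        lines = [
            "ddPCR copy-number summary",
            "=========================",
            f"samples:   {df['sample'].nunique()}",
            f"assays:    {', '.join(sorted(df['gene'].unique()))}",
            f"reference: {self.reference_assay}",
            "",
            "integer CN distribution per gene:",
        ]
        for gene, sub in df.groupby("gene"):
            counts = sub["cn_int"].value_counts().sort_index()
            parts = ", ".join(f"{cn}:{n}" for cn, n in counts.items())
            lines.append(f"  {gene:<12} {parts}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.estimates.to_csv(path, index=False)


class DdpcrAssay:
    """Poisson copy-number model for a droplet-count well table.

    Parameters
    ----------
    wells : DataFrame
        Columns ``sample, assay, total_droplets, positive_droplets`` and
        optionally ``is_ntc``; several rows per sample × assay are pooled.
    reference_assay : str
        Within-sample normalization gene (diploid copy number
        ``reference_cn``).
    """

    REQUIRED_COLUMNS = (
        "sample", "assay", "total_droplets", "positive_droplets",
    )

    def __init__(
        self,
        wells: pd.DataFrame,
        reference_assay: str = "DCL1",
        reference_cn: int = 2,
    ):
        missing = set(self.REQUIRED_COLUMNS) - set(wells.columns)
        if missing:
            raise ValueError(f"well table lacks columns: {sorted(missing)}")
        wells = wells.copy()
        if "is_ntc" not in wells.columns:
            wells["is_ntc"] = False
        if (wells["positive_droplets"] > wells["total_droplets"]).any():
            raise ValueError("positive droplets exceed total droplets")
        if (wells["total_droplets"] < 1).any():
            raise ValueError("wells must contain at least one droplet")
        self.wells = wells
        self.reference_assay = reference_assay
        self.reference_cn = reference_cn

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DdpcrAssay":
        return cls(pd.read_csv(path), **kwargs)

    def _pooled_lambda(self, sub: pd.DataFrame) -> tuple[float, int]:
        total = int(sub["total_droplets"].sum())
        positive = int(sub["positive_droplets"].sum())
        return poisson_lambda(positive, total), total

    def fit(self) -> DdpcrResults:
        wells = self.wells
        ntc = wells[wells["is_ntc"]]
        lambda_ntc = {
            assay: self._pooled_lambda(sub)[0]
            for assay, sub in ntc.groupby("assay")
        }
        samples = wells[~wells["is_ntc"]]
        if samples.empty:
            raise ValueError("no sample wells in table")

        pooled = {}
        for (sample, assay), sub in samples.groupby(["sample", "assay"]):
            lam, total = self._pooled_lambda(sub)
            lam = background_correct(lam, lambda_ntc.get(assay, 0.0))
            pooled[(sample, assay)] = (lam, total)

        rows = []
        for (sample, assay), (lam, total) in pooled.items():
            if assay == self.reference_assay:
                continue
            key = (sample, self.reference_assay)
            if key not in pooled:
                raise ValueError(
                    f"sample {sample!r} lacks reference assay "
                    f"{self.reference_assay!r}"
                )
            lam_ref, total_ref = pooled[key]
            est = copy_number(
                lam, lam_ref, self.reference_cn,
                target_droplets=total, reference_droplets=total_ref,
                sample=sample, gene=assay,
            )
            rows.append(est.__dict__)
        estimates = pd.DataFrame(rows).sort_values(
            ["sample", "gene"]).reset_index(drop=True)
        return DdpcrResults(
            estimates=estimates,
            reference_assay=self.reference_assay,
            lambda_ntc=lambda_ntc,
        )


def trichotomize_cn(cn: float, normal_cn: int = 2) -> str:
    """Collapse a copy number to del / normal / dup around ``normal_cn``."""
    if cn < normal_cn - 1:
        return "del"
    if cn > normal_cn + 1:
        return "dup"
    return "normal"


def _mlpa_gene_state(cn) -> str:
    if cn == ">=8":
        return "dup"
    if cn is None or (isinstance(cn, float) and np.isnan(cn)):
        return "NA"
    return trichotomize_cn(float(cn))


def concordance(
    mlpa_calls: pd.DataFrame,
    ddpcr_estimates: pd.DataFrame,
    mlpa_ratios: pd.DataFrame | None = None,
) -> dict:
    """Compare MLPA and ddPCR genotyping on the shared samples.

    Both call sets are trichotomized per gene (deletion / no change /
    duplication) and compared sample by sample; the report carries the
    categorical agreement fraction and, when the ratio table is given,
    the Spearman correlation between ddPCR integer copy number and the
    nearest MLPA probe ratio.
    """
    gene_to_cn_col = {
        "MSH2": "msh2_cn",
        "AT3G18530": "block_cn",
        "AT3G18535": "block_cn",
    }
    gene_to_probe = {
        "MSH2": "mlpaC", "AT3G18530": "mlpaE", "AT3G18535": "mlpaF",
    }
    shared = sorted(
        set(mlpa_calls.index) & set(ddpcr_estimates["sample"].unique())
    )
    if not shared:
        raise ValueError("no samples shared between MLPA and ddPCR sets")

    rows = []
    for _, est in ddpcr_estimates.iterrows():
        sample, gene = est["sample"], est["gene"]
        if sample not in mlpa_calls.index or gene not in gene_to_cn_col:
            continue
        mlpa_state = _mlpa_gene_state(
            mlpa_calls.loc[sample, gene_to_cn_col[gene]]
        )
        dd_state = trichotomize_cn(est["cn_float"])
        rows.append({
            "sample": sample,
            "gene": gene,
            "mlpa_state": mlpa_state,
            "ddpcr_state": dd_state,
            "ddpcr_cn": est["cn_int"],
            "mlpa_ratio": (
                mlpa_ratios.loc[sample, gene_to_probe[gene]]
                if mlpa_ratios is not None else np.nan
            ),
            "agree": mlpa_state == dd_state,
        })
    table = pd.DataFrame(rows)
    called = table[table["mlpa_state"] != "NA"]
    agreement = float(called["agree"].mean()) if len(called) else float("nan")
    rank_corr = float("nan")
    if mlpa_ratios is not None and len(called) >= 3:
        sub = called.dropna(subset=["mlpa_ratio"])
        if sub["ddpcr_cn"].nunique() > 1 and sub["mlpa_ratio"].nunique() > 1:
            rank_corr = float(stats.spearmanr(
                sub["ddpcr_cn"], sub["mlpa_ratio"]
            ).statistic)
    return {
        "n_shared_samples": len(shared),
        "n_comparisons": len(called),
        "categorical_agreement": agreement,
        "rank_correlation": rank_corr,
        "table": table,
    }
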