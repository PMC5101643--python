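"""MLPA copy-number genotyping: normalization, QC, pattern and CN calls.

The assay interrogates the locus with eight target probes (mlpaA–mlpaH)
and five control probes (ctrl1–ctrl5) on stable single-copy genes.  Peak
heights are normalized per sample to the mean of the control probes, then
expressed as ratios to a calibrator accession (Col-0, defined to carry two
copies of everything), so 1.0 ≈ two copies.  Gene states are called
against fixed thresholds (deletion < 0.5, duplication > 1.5, both strict)
and combined into one of six locus genotype patterns; integer copy
numbers come from probe-pair means, optionally de-saturated through the
inverse of the assay's concave dose response, and are only resolved up to
six copies — anything higher is reported as ">=8".

``MlpaAssay(peaks, calibrator).fit()`` runs the whole chain and returns an
:class:`MlpaResults` with the ratio table, QC report and per-sample calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TARGET_PROBES",
    "CONTROL_PROBES",
    "GENE_PROBES",
    "normalize_peaks",
    "calibrate",
    "qc_assay",
    "classify_pattern",
    "assign_integer_cn",
    "desaturate_ratio",
    "cluster_panel",
    "MlpaAssay",
    "MlpaResults",
]

TARGET_PROBES = tuple(f"mlpa{c}" for c in "ABCDEFGH")
CONTROL_PROBES = tuple(f"ctrl{i}" for i in range(1, 6))

#: probe pairs used for integer copy-number assignment per gene; the block
#: CN is called from the interior probes mlpaE/mlpaF (the outer probes
#: mlpaD/mlpaG sit near the variable breakpoints and feed the discordance
#: flag instead).
GENE_PROBES = {
    "MSH2": ("mlpaB", "mlpaC"),
    "block": ("mlpaE", "mlpaF"),
}

#: probes averaged for the categorical del/normal/dup gene state
STATE_PROBES = {
    "MSH2": ("mlpaB", "mlpaC"),
    "block": ("mlpaD", "mlpaE", "mlpaF", "mlpaG"),
}

DEFAULT_THRESHOLDS = {"del": 0.5, "dup": 1.5}


def _check_probes(table: pd.DataFrame, control_probes) -> None:
    missing = set(TARGET_PROBES) | set(control_probes)
    missing -= set(table.columns)
    if missing:
        raise ValueError(f"peak table lacks probes: {sorted(missing)}")


def normalize_peaks(
    peaks: pd.DataFrame,
    control_probes=CONTROL_PROBES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample's peaks by its mean control-probe height.

    Returns ``(normalized, excluded)`` where ``excluded`` flags samples
    with a zero or missing control probe (their rows are NaN and must not
    be called).  After normalization the control probes of every retained
    sample average exactly 1.0.
    """
    _check_probes(peaks, control_probes)
    if (peaks.to_numpy(dtype=float) < 0).any():
        raise ValueError("peak heights must be non-negative")
    ctrl = peaks[list(control_probes)].astype(float)
    bad = ctrl.isna().any(axis=1) | (ctrl <= 0).any(axis=1)
    denom = ctrl.mean(axis=1)
    normalized = peaks.astype(float).div(denom, axis=0)
    normalized[bad] = np.nan
    return normalized, bad


def calibrate(
    normalized: pd.DataFrame,
    calibrator_id: str,
) -> pd.DataFrame:
    """Express normalized signals as ratios to the calibrator accession."""
    if calibrator_id not in normalized.index:
        raise ValueError(f"calibrator {calibrator_id!r} not in table")
    ref = normalized.loc[calibrator_id]
    if ref.isna().any():
        raise ValueError("calibrator failed normalization")
    if (ref == 0).any():
        raise ValueError("calibrator has zero-signal probes")
    return normalized.div(ref, axis=1)


def qc_assay(
    ratios: pd.DataFrame,
    control_probes=CONTROL_PROBES,
    max_cv: float = 0.10,
    ratio_range: tuple[float, float] = (0.8, 1.2),
) -> pd.DataFrame:
    """Per-sample control-probe QC.

    FAIL when the control-probe coefficient of variation reaches
    ``max_cv`` (the assay's <10% reproducibility bound); WARN when any
    control ratio leaves ``ratio_range`` (such samples are retained —
    observed deviations up to 0.67/1.38 on a single probe are tolerable);
    PASS otherwise.  Report-only: nothing is dropped here.
    """
    ctrl = ratios[list(control_probes)].astype(float)
    mean = ctrl.mean(axis=1)
    cv = ctrl.std(axis=1, ddof=0) / mean
    lo, hi = ratio_range
    n_out = ((ctrl < lo) | (ctrl > hi)).sum(axis=1)
    status = pd.Series("PASS", index=ratios.index)
    status[n_out > 0] = "WARN"
    status[(cv >= max_cv) | cv.isna()] = "FAIL"
    return pd.DataFrame({
        "control_cv": cv,
        "control_min": ctrl.min(axis=1),
        "control_max": ctrl.max(axis=1),
        "n_out_of_range": n_out,
        "status": status,
    })


def _gene_state(mean_ratio: float, thresholds) -> str:
    if np.isnan(mean_ratio):
        return "NA"
    if mean_ratio < thresholds["del"]:
        return "del"
    if mean_ratio > thresholds["dup"]:
        return "dup"
    return "normal"


_PATTERN_MAP = {
    ("normal", "normal"): "basic",
    ("normal", "del"): "del-2",
    ("dup", "normal"): "dupl-1",
    ("normal", "dup"): "dupl-2",
    ("dup", "dup"): "dupl-3-a",
}


def classify_pattern(
    ratios: pd.DataFrame,
    thresholds: dict | None = None,
    dupl3b_factor: float = 1.5,
) -> pd.DataFrame:
    """Assign each sample one of the six locus CNV patterns.

    Gene states come from probe means (MSH2: mlpaB/C; block: mlpaD–G);
    (dup, dup) upgrades from dupl-3-a to dupl-3-b when the mlpaD ratio
    exceeds ``dupl3b_factor`` times the mean of mlpaE–G.  An MSH2
    deletion state has never been observed at this locus; it is still
    reported, flagged as an unobserved genotype.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    msh2_mean = ratios[list(STATE_PROBES["MSH2"])].mean(axis=1)
    block_mean = ratios[list(STATE_PROBES["block"])].mean(axis=1)
    out = []
    for sample in ratios.index:
        s_m = _gene_state(msh2_mean.loc[sample], thresholds)
        s_b = _gene_state(block_mean.loc[sample], thresholds)
        note = ""
        if "NA" in (s_m, s_b):
            pattern = "NA"
        elif s_m == "del":
            pattern = f"unobserved({s_m},{s_b})"
            note = "unobserved genotype: MSH2 deletion state"
        else:
            pattern = _PATTERN_MAP[(s_m, s_b)]
            if pattern == "dupl-3-a":
                d = ratios.loc[sample, "mlpaD"]
                efg = ratios.loc[sample, ["mlpaE", "mlpaF", "mlpaG"]].mean()
                if d > dupl3b_factor * efg:
                    pattern = "dupl-3-b"
        out.append({
            "sample": sample,
            "msh2_state": s_m,
            "block_state": s_b,
            "pattern": pattern,
            "note": note,
        })
    return pd.DataFrame(out).set_index("sample")


def desaturate_ratio(ratio: float, saturation: float) -> float:
    """Invert the saturating dose response ``r = x / (1 + σ(x − 1))``.

    ``x`` is copy number in units of two copies; ratios at or beyond the
    response's horizontal asymptote map to +inf.
    """
    if saturation == 0:
        return ratio
    denom = 1.0 - ratio * saturation
    if denom <= 0:
        return np.inf
    return ratio * (1.0 - saturation) / denom


def assign_integer_cn(
    ratio_pair: tuple[float, float],
    saturation_inverse: float | None = None,
    max_resolved_cn: int = 6,
    discordance_gap: float = 0.5,
) -> tuple[int | str, bool]:
    """Map a probe-ratio pair to an even integer copy number.

    The pair mean (optionally de-saturated) is doubled and rounded to the
    nearest even integer; values beyond ``max_resolved_cn`` collapse to
    ``">=8"`` since cluster spacing shrinks with copy number and the assay
    cannot resolve further.  Returns ``(cn, discordant)`` where the flag
    marks pairs differing by more than ``discordance_gap`` with neither
    ratio near zero (probe dropout or breakpoint interference).
    """
    r1, r2 = ratio_pair
    if any(np.isnan([r1, r2])):
        raise ValueError("both probe ratios are required")
    discordant = abs(r1 - r2) > discordance_gap and min(r1, r2) > 0.2
    mean = (r1 + r2) / 2.0
    if saturation_inverse:
        mean = desaturate_ratio(mean, saturation_inverse)
    cn_val = 2.0 * mean
    if not np.isfinite(cn_val) or cn_val > max_resolved_cn + 1:
        return ">=8", discordant
    cn = int(2 * round(cn_val / 2.0))
    cn = max(cn, 0)
    if cn > max_resolved_cn:
        return ">=8", discordant
    return cn, discordant


def cluster_panel(
    pair_means: pd.Series,
    calibrator_id: str,
    min_gap: float = 0.35,
    saturation: float | None = None,
    del_threshold: float = 0.5,
    max_resolved_cn: int = 6,
) -> tuple[pd.Series, dict]:
    """Deterministic 1-D clustering of a probe-pair ratio across a panel.

    Samples are sorted by mean pair ratio and split wherever consecutive
    values differ by more than ``min_gap``; clusters are labelled 0, 2, 4,
    6 or ">=8" by ascending mean, anchored so the calibrator's cluster is
    labelled 2.  On well-separated data this reproduces per-sample
    :func:`assign_integer_cn` calls.
    """
    if calibrator_id not in pair_means.index:
        raise ValueError(f"calibrator {calibrator_id!r} not in panel")
    order = pair_means.sort_values().index
    values = pair_means.loc[order].to_numpy(dtype=float)
    cluster_of = {}
    cid = 0
    for i, sample in enumerate(order):
        if i > 0 and values[i] - values[i - 1] > min_gap:
            cid += 1
        cluster_of[sample] = cid
    n_clusters = cid + 1
    means = np.array([
        values[[cluster_of[s] == c for s in order]].mean()
        for c in range(n_clusters)
    ])
    cal_cluster = cluster_of[calibrator_id]

    labels: dict[int, int | str] = {cal_cluster: 2}
    for c in range(n_clusters):
        if c == cal_cluster:
            continue
        m = means[c]
        if m < del_threshold and c < cal_cluster:
            labels[c] = 0
            continue
        x = desaturate_ratio(m, saturation) if saturation else m
        cn_val = 2.0 * x
        if not np.isfinite(cn_val) or cn_val > max_resolved_cn + 1:
            labels[c] = ">=8"
            continue
        cn = max(int(2 * round(cn_val / 2.0)), 0)
        labels[c] = cn if cn <= max_resolved_cn else ">=8"

    # enforce strictly increasing labels with ascending cluster mean
    prev = None
    for c in range(n_clusters):
        lab = labels[c]
        if prev is not None and lab != ">=8" and prev != ">=8":
            if lab <= prev:
                lab = prev + 2
                labels[c] = lab if lab <= max_resolved_cn else ">=8"
        prev = labels[c] if labels[c] != ">=8" else prev
    assignments = pd.Series(
        {s: labels[cluster_of[s]] for s in pair_means.index},
        index=pair_means.index, name="cn",
    )
    cluster_means = {labels[c]: float(means[c]) for c in range(n_clusters)}
    return assignments, cluster_means


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class MlpaResults:
    """Fitted MLPA panel: calibrated ratios, QC report and genotype calls.

    ``calls`` has one row per sample with the six-class pattern, per-gene
    integer copy numbers (">=8" beyond the assay's resolution) and
    discordance/QC flags.
    """

    ratios: pd.DataFrame
    qc: pd.DataFrame
    calls: pd.DataFrame
    calibrator_id: str
    excluded: pd.Series = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "MLPA panel genotyping summary",
            "=============================",
            f"samples:            {len(self.calls)}",
            f"calibrator:         {self.calibrator_id}",
            f"QC PASS/WARN/FAIL:  "
            f"{(self.qc['status'] == 'PASS').sum()}/"
            f"{(self.qc['status'] == 'WARN').sum()}/"
            f"{(self.qc['status'] == 'FAIL').sum()}",
            "",
            "pattern counts:",
        ]
        for pat, n in self.calls["pattern"].value_counts().items():
            pct = 100.0 * n / len(self.calls)
            lines.append(f"  {pat:<12} {n:>4}  ({pct:.1f} %)")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.calls.join(self.qc[["control_cv", "status"]]).to_csv(path)


class MlpaAssay:
    """MLPA genotyping model for a peak-height table.

    Parameters
    ----------
    peaks : DataFrame
        Samples × probes raw peak heights; must contain mlpaA–mlpaH and
        the control probes.
    calibrator : str
        Sample defined to carry two copies of every target (ratio 1.0).
    saturation : float, optional
        Saturation parameter of the assay's dose response; when given,
        ratios are de-saturated before integer CN assignment.
    """

    def __init__(
        self,
        peaks: pd.DataFrame,
        calibrator: str = "Col-0",
        control_probes=CONTROL_PROBES,
        thresholds: dict | None = None,
        dupl3b_factor: float = 1.5,
        saturation: float | None = None,
    ):
        _check_probes(peaks, control_probes)
        self.peaks = peaks
        self.calibrator = calibrator
        self.control_probes = tuple(control_probes)
        self.thresholds = thresholds or dict(DEFAULT_THRESHOLDS)
        self.dupl3b_factor = dupl3b_factor
        self.saturation = saturation

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MlpaAssay":
        peaks = pd.read_csv(path, index_col=0)
        return cls(peaks, **kwargs)

    def fit(self) -> MlpaResults:
        normalized, excluded = normalize_peaks(self.peaks, self.control_probes)
        ratios = calibrate(normalized, self.calibrator)
        qc = qc_assay(ratios, self.control_probes)
        patterns = classify_pattern(
            ratios, self.thresholds, self.dupl3b_factor
        )

        rows = []
        for sample in ratios.index:
            if excluded.loc[sample]:
                rows.append({
                    "sample": sample, "pattern": "NA", "msh2_cn": None,
                    "block_cn": None, "msh2_discordant": False,
                    "block_discordant": False,
                    "note": "excluded: control probe missing/zero",
                })
                continue
            cns = {}
            flags = {}
            for gene, (p1, p2) in GENE_PROBES.items():
                cn, disc = assign_integer_cn(
                    (ratios.loc[sample, p1], ratios.loc[sample, p2]),
                    saturation_inverse=self.saturation,
                )
                cns[gene] = cn
                flags[gene] = disc
            rows.append({
                "sample": sample,
                "pattern": patterns.loc[sample, "pattern"],
                "msh2_cn": cns["MSH2"],
                "block_cn": cns["block"],
                "msh2_discordant": flags["MSH2"],
                "block_discordant": flags["block"],
                "note": patterns.loc[sample, "note"],
            })
        calls = pd.DataFrame(rows).set_index("sample")
        n_fail = int((qc["status"] == "FAIL").sum())
        if n_fail:
            warnings.warn(
                f"{n_fail} sample(s) failed control-probe QC",
                stacklevel=2,
            )
        return MlpaResults(
            ratios=ratios, qc=qc, calls=calls,
            calibrator_id=self.calibrator, excluded=excluded,
        )
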