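"""Synthetic accession panels for the NAHR-driven multiallelic CNV locus.

Every generator is a pure function of ``(config, seed)``: the same seed
yields bit-identical output.  The default :class:`PanelConfig` mirrors the
structure of a 189-accession genotyping study of this locus — 67 basic,
101 del-2, 1 dupl-1, 9 dupl-2, 6 dupl-3-a and 5 dupl-3-b accessions, with
copy numbers spanning 0 to 14 — so downstream callers can be exercised
against known truth without any external data.

Generated artefacts:

- reference segment with two planted 1238-bp LCR copies (11 PSVs),
- per-accession rearranged sequences and junction amplicons,
- MLPA peak tables with saturating dose response and lognormal noise,
- ddPCR droplet counts (binomial sampling of Poisson positive fractions),
- N-masked pseudogenomes (deletion accessions lose the block region),
- bi-allelic SNP matrices over the two 20-kb flanks, CNV-independent
  by default so that LD against CNV genotype stays at noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from athcnv.locus import (
    GenomicInterval,
    LcrPair,
    LocusMap,
    default_locus_map,
    nahr_deletion_size,
    psv_intervals,
)

__all__ = [
    "PATTERNS",
    "AccessionProfile",
    "PanelConfig",
    "simulate_panel",
    "panel_to_frame",
    "simulate_reference",
    "simulate_accession_sequence",
    "simulate_junction_amplicon",
    "recombinant_lcr",
    "simulate_mlpa_peaks",
    "simulate_ddpcr_wells",
    "simulate_pseudogenome",
    "simulate_snp_matrix",
    "TARGET_PROBES",
    "CONTROL_PROBES",
    "DDPCR_ASSAYS",
]

PATTERNS = ("basic", "del-2", "dupl-1", "dupl-2", "dupl-3-a", "dupl-3-b")

TARGET_PROBES = tuple(f"mlpa{c}" for c in "ABCDEFGH")
CONTROL_PROBES = tuple(f"ctrl{i}" for i in range(1, 6))

# ddPCR assays: three CNV genes, two stable flanking genes, one reference.
DDPCR_ASSAYS = ("MSH2", "AT3G18530", "AT3G18535", "HDA15", "BRC1", "DCL1")

# Sampling regions of a 189-accession panel (used as country labels).
COUNTRIES = (
    "Iberian Peninsula & Morocco", "Western Europe", "Alps", "Italy",
    "Northern Europe", "Central & Southeast Europe", "Eastern Europe",
    "Western Asia & Caucasus", "Central Asia", "East Asia",
    "Pacific Northwest", "Midwest",
)

_BASES = np.array(list("ACGT"))

EXTENSION_BP = 790  # extended-duplication tail beyond the right LCR
MICROHOMOLOGY_BP = 9


@dataclass(frozen=True)
class AccessionProfile:
    """Ground truth for one simulated accession (homozygous inbred line)."""

    accession_id: str
    genotype_pattern: str
    msh2_cn: int
    block_cn: int
    breakpoint_interval: int | None = None
    conversion_sites: tuple[int, ...] = ()
    extended_duplication: bool = False
    country: str = ""

    def __post_init__(self) -> None:
        p = self.genotype_pattern
        if p not in PATTERNS:
            raise ValueError(f"unknown genotype pattern {p!r}")
        for cn in (self.msh2_cn, self.block_cn):
            if cn < 0 or cn % 2:
                raise ValueError("copy numbers must be non-negative and even")
        if self.msh2_cn == 0:
            raise ValueError("MSH2 is never deleted in this model")
        ok = {
            "basic": self.msh2_cn == 2 and self.block_cn == 2,
            "del-2": self.msh2_cn == 2 and self.block_cn == 0,
            "dupl-1": self.msh2_cn >= 4 and self.block_cn == 2,
            "dupl-2": self.msh2_cn == 2 and self.block_cn >= 4,
            "dupl-3-a": self.msh2_cn >= 4 and self.block_cn >= 4,
            "dupl-3-b": self.msh2_cn >= 4 and self.block_cn >= 4,
        }[p]
        if not ok:
            raise ValueError(
                f"copy numbers ({self.msh2_cn},{self.block_cn}) inconsistent "
                f"with pattern {p!r}"
            )
        if p in ("del-2", "dupl-2") and self.breakpoint_interval is None:
            raise ValueError(f"{p} requires a breakpoint interval")
        if self.extended_duplication and p != "dupl-2":
            raise ValueError("extended duplication only applies to dupl-2")


# Per-pattern copy-number rosters.  Cycled over the accessions of each
# pattern, they reproduce the per-gene cluster structure of the study
# panel: MSH2 2/4/6/>=8 in 177/5/2/5 accessions and block 0/2/4/6/>=8 in
# 101/68/10/3/7 accessions at the default pattern counts.
_DEFAULT_MSH2_CN = {
    "basic": (2,),
    "del-2": (2,),
    "dupl-1": (4,),
    "dupl-2": (2,),
    "dupl-3-a": (4, 4, 6, 8, 8, 12),
    "dupl-3-b": (4, 4, 6, 8, 14),
}
_DEFAULT_BLOCK_CN = {
    "basic": (2,),
    "del-2": (0,),
    "dupl-1": (2,),
    "dupl-2": (4, 4, 4, 4, 4, 4, 6, 8, 12),
    "dupl-3-a": (4, 4, 4, 6, 6, 8),
    "dupl-3-b": (4, 8, 10, 12, 14),
}
_DEFAULT_PATTERN_COUNTS = {
    "basic": 67, "del-2": 101, "dupl-1": 1,
    "dupl-2": 9, "dupl-3-a": 6, "dupl-3-b": 5,
}


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for the synthetic panel.

    MLPA noise CV defaults to 5% per measurement (comfortably inside the
    <10% control-probe SD the assay QC demands) with a 10% lognormal
    per-sample scaling factor so control-probe normalization does real
    work.  ddPCR wells hold ~18,000 droplets; ``lambda_ref`` is the mean
    copies-per-droplet of a two-copy locus.
    """

    n_accessions: int = 189
    pattern_frequencies: dict = field(
        default_factory=lambda: {
            k: v / 189 for k, v in _DEFAULT_PATTERN_COUNTS.items()
        }
    )
    msh2_cn_choices: dict = field(default_factory=lambda: dict(_DEFAULT_MSH2_CN))
    block_cn_choices: dict = field(default_factory=lambda: dict(_DEFAULT_BLOCK_CN))
    # MLPA
    mlpa_noise_cv: float = 0.05
    mlpa_saturation: float = 0.108
    mlpa_background: float = 0.01
    mlpa_base_signal: float = 1000.0
    sample_scale_cv: float = 0.10
    dupl3b_mlpad_boost: float = 2.0
    # ddPCR
    droplets_per_well: int = 18000
    n_wells: int = 3
    lambda_ref: float = 0.3
    lambda_ntc: float = 0.001
    # pseudogenomes
    pseudogenome_n_noise: float = 0.03
    # SNP matrix
    n_snps: int = 200
    maf_min: float = 0.10
    maf_max: float = 0.50
    snp_missing_rate: float = 0.05
    ld_rho: float = 0.0
    # breakpoints
    del2_conversion_fraction: float = 0.07
    dupl2_conversion_fraction: float = 0.40
    dupl2_extended_fraction: float = 0.33
    calibrator_id: str = "Col-0"

    def __post_init__(self) -> None:
        total = sum(self.pattern_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pattern frequencies must sum to 1")
        for name in (
            "mlpa_noise_cv", "mlpa_background", "sample_scale_cv",
            "pseudogenome_n_noise", "snp_missing_rate", "ld_rho",
            "del2_conversion_fraction", "dupl2_conversion_fraction",
            "dupl2_extended_fraction",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.mlpa_saturation < 1:
            raise ValueError("mlpa_saturation must be in [0, 1)")
        if self.pseudogenome_n_noise > 0.2:
            raise ValueError("pseudogenome_n_noise must be <= 0.2")
        if self.droplets_per_well < 1:
            raise ValueError("droplets_per_well must be >= 1")
        if self.lambda_ref < 0 or self.lambda_ntc < 0:
            raise ValueError("droplet rates must be non-negative")


def _counts_from_frequencies(freqs: dict, n: int) -> dict:
    """Largest-remainder apportionment of n accessions across patterns."""
    raw = {k: freqs[k] * n for k in PATTERNS if freqs.get(k, 0) > 0}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def simulate_panel(
    config: PanelConfig | None = None, seed: int = 0
) -> list[AccessionProfile]:
    """Draw a panel of accession truth profiles.

    The calibrator accession (``Col-0``, basic, CN 2/2) is always the
    first entry and is part of the requested panel size.
    """
    config = config or PanelConfig()
    rng = np.random.default_rng(seed)
    counts = _counts_from_frequencies(
        config.pattern_frequencies, config.n_accessions
    )
    # the calibrator is itself a basic accession and is emitted separately
    counts["basic"] = max(counts.get("basic", 1) - 1, 0)
    n_intervals = len(psv_intervals(LcrPair(
        GenomicInterval("x", 1, 1238), GenomicInterval("x", 2000, 3237)
    )))

    profiles = [AccessionProfile(
        accession_id=config.calibrator_id,
        genotype_pattern="basic", msh2_cn=2, block_cn=2,
        country="Western Europe",
    )]
    idx = 1
    for pattern in PATTERNS:
        n_pat = counts.get(pattern, 0)
        msh2_list = config.msh2_cn_choices[pattern]
        block_list = config.block_cn_choices[pattern]
        for j in range(n_pat):
            bp_interval = None
            conv: tuple[int, ...] = ()
            extended = False
            if pattern == "del-2":
                # breakpoints of deletion junctions fall in the first
                # PSV-delimited interval
                bp_interval = 1
                if rng.random() < config.del2_conversion_fraction:
                    conv = (int(rng.integers(3, 9)),)
            elif pattern == "dupl-2":
                # duplication junctions fall mostly in the second interval
                bp_interval = 2 if rng.random() < 0.85 else int(
                    rng.integers(3, n_intervals + 1)
                )
                if rng.random() < config.dupl2_conversion_fraction:
                    conv = (int(rng.integers(5, 10)),)
                extended = rng.random() < config.dupl2_extended_fraction
            profiles.append(AccessionProfile(
                accession_id=f"acc{idx:04d}",
                genotype_pattern=pattern,
                msh2_cn=msh2_list[j % len(msh2_list)],
                block_cn=block_list[j % len(block_list)],
                breakpoint_interval=bp_interval,
                conversion_sites=conv,
                extended_duplication=extended,
                country=COUNTRIES[int(rng.integers(len(COUNTRIES)))],
            ))
            idx += 1
    return profiles


def panel_to_frame(panel: Sequence[AccessionProfile]) -> pd.DataFrame:
    """Truth panel as a DataFrame (one row per accession)."""
    rows = [asdict(p) for p in panel]
    df = pd.DataFrame(rows).set_index("accession_id")
    df["conversion_sites"] = df["conversion_sites"].apply(
        lambda t: ",".join(map(str, t))
    )
    return df


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def simulate_reference(
    locus: LocusMap | None = None, seed: int = 0
) -> tuple[str, LocusMap]:
    """Random reference segment with the two LCR copies planted.

    The two repeat copies are identical except at the configured PSVs, so
    their pairwise identity is ``(alignment_length − n_psv) /
    alignment_length`` (99.11% at the defaults).  The LCR sequence occurs
    nowhere else in the segment.  A 9-nt microhomology between the end of
    the +790-bp extension window and the 3' border of the left LCR is also
    planted, supporting extended-duplication junction simulation.
    """
    locus = locus or default_locus_map()
    rng = np.random.default_rng(seed)
    region = locus.region
    lcr = locus.lcr
    n = region.length
    seq = _random_bases(rng, n)

    def idx(pos: int) -> int:
        return pos - region.start

    left_lcr = _random_bases(rng, lcr.alignment_length)
    for p, a in zip(lcr.psv_positions, lcr.left_alleles):
        left_lcr[p - 1] = a
    right_lcr = left_lcr.copy()
    for p, a in zip(lcr.psv_positions, lcr.right_alleles):
        right_lcr[p - 1] = a

    seq[idx(lcr.left.start): idx(lcr.left.end) + 1] = left_lcr
    seq[idx(lcr.right.start): idx(lcr.right.end) + 1] = right_lcr

    # 9-nt microhomology: the last 9 bases of the +790 bp extension window
    # beyond the right LCR copy the 3' border of the left LCR; the base
    # just before is forced to differ so the match length is exactly 9.
    ext_end = idx(lcr.right.end) + EXTENSION_BP
    border = seq[idx(lcr.left.end) - MICROHOMOLOGY_BP + 1: idx(lcr.left.end) + 1]
    seq[ext_end - MICROHOMOLOGY_BP + 1: ext_end + 1] = border
    pre_ext = seq[ext_end - MICROHOMOLOGY_BP]
    pre_ref = seq[idx(lcr.left.end) - MICROHOMOLOGY_BP]
    if pre_ext == pre_ref:
        seq[ext_end - MICROHOMOLOGY_BP] = _BASES[
            (np.where(_BASES == pre_ext)[0][0] + 1) % 4
        ]

    lcr_with_seq = replace(lcr, alignment_seq="".join(left_lcr))
    locus_with_seq = LocusMap(
        region=locus.region,
        genes=locus.genes,
        lcr=lcr_with_seq,
        probe_targets=locus.probe_targets,
        primer_anchors=locus.primer_anchors,
        dup_junction_amplicon_bp=locus.dup_junction_amplicon_bp,
    )
    return "".join(seq), locus_with_seq


def recombinant_lcr(
    lcr: LcrPair,
    breakpoint_interval: int,
    junction_type: str,
    conversion_sites: Sequence[int] = (),
) -> str:
    """Sequence of the chimeric repeat created by a strand exchange.

    For a deletion junction the repeat reads left-alleles up to the
    breakpoint interval and right-alleles after it; duplication junctions
    are the reciprocal (right then left).  ``conversion_sites`` (1-based
    PSV indices) toggle individual PSVs, modelling discontinuous gene
    conversion.
    """
    n_int = len(psv_intervals(lcr))
    if not 1 <= breakpoint_interval <= n_int:
        raise ValueError(
            f"breakpoint interval must be in 1..{n_int}, "
            f"got {breakpoint_interval}"
        )
    if junction_type not in ("deletion", "duplication"):
        raise ValueError(f"unknown junction type {junction_type!r}")
    seq = list(lcr.left_seq())
    for i, (p, la, ra) in enumerate(
        zip(lcr.psv_positions, lcr.left_alleles, lcr.right_alleles), start=1
    ):
        before_switch = i < breakpoint_interval
        if junction_type == "deletion":
            allele = la if before_switch else ra
        else:
            allele = ra if before_switch else la
        if i in conversion_sites:
            allele = ra if allele == la else la
        seq[p - 1] = allele
    return "".join(seq)


def simulate_accession_sequence(
    profile: AccessionProfile,
    reference: str,
    locus: LocusMap,
    seed: int = 0,
) -> str:
    """Rearranged genomic segment for one accession (one haplotype).

    Accessions are homozygous, so a single haplotype represents the
    genome.  del-2 removes one repeat plus the intervening block and
    leaves a recombinant repeat; dupl-2 inserts head-to-tail copies of the
    repeat+block unit with recombinant repeats at the internal junctions;
    MSH2 duplications are modelled as plain tandem copies of the gene
    body (their mechanism is not dissected here).
    """
    region = locus.region
    lcr = locus.lcr

    def idx(pos: int) -> int:
        return pos - region.start

    p = profile.genotype_pattern
    if p == "basic":
        return reference

    if p == "del-2":
        recomb = recombinant_lcr(
            lcr, profile.breakpoint_interval, "deletion",
            profile.conversion_sites,
        )
        return (
            reference[: idx(lcr.left.start)]
            + recomb
            + reference[idx(lcr.right.end) + 1:]
        )

    seq = reference
    if p in ("dupl-2", "dupl-3-a", "dupl-3-b") and profile.block_cn >= 4:
        n_extra = profile.block_cn // 2 - 1
        bp_int = profile.breakpoint_interval or 2
        junction = recombinant_lcr(
            lcr, bp_int, "duplication", profile.conversion_sites
        )
        # unit between the repeat copies: block genes + spacer
        block = reference[idx(lcr.left.end) + 1: idx(lcr.right.start)]
        if profile.extended_duplication:
            ext = reference[
                idx(lcr.right.end) + 1: idx(lcr.right.end) + 1 + EXTENSION_BP
            ]
            # duplicated fragment runs through the right LCR and 790 bp
            # beyond, rejoining at the left LCR 3' border via the 9-nt
            # microhomology (the block then follows as in the reference)
            insert = lcr.right_seq() + ext + block
        else:
            insert = junction + block
        seq = (
            seq[: idx(lcr.right.start)]
            + insert * n_extra
            + seq[idx(lcr.right.start):]
        )

    if p in ("dupl-1", "dupl-3-a", "dupl-3-b") and profile.msh2_cn >= 4:
        g = locus.genes["MSH2"]
        n_extra = profile.msh2_cn // 2 - 1
        gene_seq = reference[idx(g.start): idx(g.end) + 1]
        insert_at = idx(g.end) + 1
        # sequence may have grown upstream-invariantly (MSH2 precedes the
        # LCRs, so earlier coordinates are unshifted)
        seq = seq[:insert_at] + gene_seq * n_extra + seq[insert_at:]
    return seq


def simulate_junction_amplicon(
    profile: AccessionProfile,
    reference: str,
    locus: LocusMap,
    flank: int = 300,
) -> str:
    """Breakpoint-spanning amplicon sequence for a del-2/dupl-2 accession.

    Deletion junctions carry the left repeat's upstream flank and the
    right repeat's downstream flank around one recombinant repeat;
    duplication junctions the reciprocal flank arrangement (block sequence
    on both sides in tail-to-head orientation).
    """
    region = locus.region
    lcr = locus.lcr

    def idx(pos: int) -> int:
        return pos - region.start

    if profile.genotype_pattern == "del-2":
        recomb = recombinant_lcr(
            lcr, profile.breakpoint_interval, "deletion",
            profile.conversion_sites,
        )
        up = reference[idx(lcr.left.start) - flank: idx(lcr.left.start)]
        down = reference[idx(lcr.right.end) + 1: idx(lcr.right.end) + 1 + flank]
        return up + recomb + down
    if profile.genotype_pattern == "dupl-2":
        recomb = recombinant_lcr(
            lcr, profile.breakpoint_interval, "duplication",
            profile.conversion_sites,
        )
        # tail-to-head: upstream of the junction repeat lies the end of the
        # first block copy (= right LCR's upstream), downstream the start of
        # the second copy (= left LCR's downstream)
        up = reference[idx(lcr.right.start) - flank: idx(lcr.right.start)]
        down = reference[idx(lcr.left.end) + 1: idx(lcr.left.end) + 1 + flank]
        return up + recomb + down
    raise ValueError(
        "junction amplicons exist only for del-2/dupl-2 genotypes"
    )


# ---------------------------------------------------------------------------
# MLPA peaks
# ---------------------------------------------------------------------------

def mlpa_expected_signal(
    cn: int | float,
    s0: float = 1.0,
    saturation: float = 0.0,
    background: float = 0.01,
) -> float:
    """Saturating MLPA dose response.

    ``S(c) = s0 · (c/2) / (1 + σ·(c/2 − 1))`` for c ≥ 2 (σ = 0 is linear);
    zero copies give a small background signal.  The concave response
    reproduces the shrinking cluster spacing at high copy number that
    limits MLPA's resolution beyond ~8 copies.
    """
    if cn <= 0:
        return s0 * background
    half = cn / 2.0
    return s0 * half / (1.0 + saturation * (half - 1.0))


def _probe_copy_number(probe: str, profile: AccessionProfile) -> int:
    if probe in ("mlpaB", "mlpaC"):
        return profile.msh2_cn
    if probe in ("mlpaD", "mlpaE", "mlpaF", "mlpaG"):
        return profile.block_cn
    return 2  # mlpaA (HDA15), mlpaH (BRC1) and the five control probes


def simulate_mlpa_peaks(
    panel: Sequence[AccessionProfile],
    config: PanelConfig | None = None,
    locus: LocusMap | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw MLPA peak-height table (samples × probes).

    Multiplicative lognormal noise at the configured CV per measurement,
    one lognormal scaling factor per sample (ligation/pipetting
    efficiency), and a boosted mlpaD signal for dupl-3-b accessions.
    """
    config = config or PanelConfig()
    if config.mlpa_noise_cv < 0:
        raise ValueError("mlpa_noise_cv must be >= 0")
    if not any(
        p.genotype_pattern == "basic" and p.accession_id == config.calibrator_id
        for p in panel
    ):
        raise ValueError(
            f"panel must include the calibrator {config.calibrator_id!r} "
            "with the basic genotype"
        )
    rng = np.random.default_rng(seed)
    probes = list(TARGET_PROBES) + list(CONTROL_PROBES)

    def lognormal_factor(cv: float, size=None):
        if cv <= 0:
            return 1.0 if size is None else np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    rows = {}
    for prof in panel:
        scale = lognormal_factor(config.sample_scale_cv)
        vals = []
        for probe in probes:
            cn = _probe_copy_number(probe, prof)
            s = mlpa_expected_signal(
                cn,
                s0=config.mlpa_base_signal,
                saturation=config.mlpa_saturation,
                background=config.mlpa_background,
            )
            if probe == "mlpaD" and prof.genotype_pattern == "dupl-3-b":
                s *= config.dupl3b_mlpad_boost
            vals.append(s * scale * lognormal_factor(config.mlpa_noise_cv))
        rows[prof.accession_id] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=probes)
    df.index.name = "sample"
    return df


# ---------------------------------------------------------------------------
# ddPCR droplets
# ---------------------------------------------------------------------------

def _assay_copy_number(assay: str, profile: AccessionProfile) -> int:
    if assay == "MSH2":
        return profile.msh2_cn
    if assay in ("AT3G18530", "AT3G18535"):
        return profile.block_cn
    return 2  # HDA15, BRC1 flanking controls and the DCL1 reference


def simulate_ddpcr_wells(
    panel: Sequence[AccessionProfile],
    config: PanelConfig | None = None,
    seed: int = 0,
    assays: Sequence[str] = DDPCR_ASSAYS,
) -> pd.DataFrame:
    """Droplet-count table: one row per sample × assay × replicate well.

    Positive droplets are ``Binomial(N, 1 − e^(−λ))`` with
    ``λ = λ_ref · c/2`` for the assay's copy number c; no-template
    control (NTC) wells use ``λ_ntc``.
    """
    config = config or PanelConfig()
    if config.droplets_per_well < 1:
        raise ValueError("droplets per well must be >= 1")
    rng = np.random.default_rng(seed)
    records = []

    def wells(sample, assay, lam, is_ntc):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        p = 1.0 - np.exp(-lam)
        for w in range(config.n_wells):
            pos = int(rng.binomial(config.droplets_per_well, p))
            records.append({
                "sample": sample,
                "assay": assay,
                "well": w + 1,
                "total_droplets": config.droplets_per_well,
                "positive_droplets": pos,
                "is_ntc": is_ntc,
            })

    for prof in panel:
        for assay in assays:
            cn = _assay_copy_number(assay, prof)
            wells(prof.accession_id, assay, config.lambda_ref * cn / 2.0, False)
    for assay in assays:
        wells("NTC", assay, config.lambda_ntc, True)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# pseudogenomes
# ---------------------------------------------------------------------------

def simulate_pseudogenome(
    profile: AccessionProfile,
    reference: str,
    locus: LocusMap,
    n_noise_rate: float = 0.03,
    seed: int = 0,
) -> str:
    """Reference-projected pseudogenome with uncalled sites as N.

    del-2 accessions lose the repeat+block span, so short-read callers
    leave the whole deleted region uncalled: it is fully N-masked here.
    All accessions additionally receive background N noise at
    ``n_noise_rate`` (uncalled sites scattered through the segment).
    """
    if not 0 <= n_noise_rate <= 0.2:
        raise ValueError("n_noise_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    region = locus.region
    seq = np.array(list(reference))
    if n_noise_rate > 0:
        mask = rng.random(len(seq)) < n_noise_rate
        seq[mask] = "N"
    if profile.genotype_pattern == "del-2":
        span = locus.deleted_span
        seq[span.start - region.start: span.end - region.start + 1] = "N"
    return "".join(seq)


# ---------------------------------------------------------------------------
# SNP matrix
# ---------------------------------------------------------------------------

#: 20-kb flanking windows screened for SNPs on either side of the CNV.
SNP_FLANKS = (
    GenomicInterval("Chr3", 6348000, 6368000),
    GenomicInterval("Chr3", 6380000, 6400000),
)


def simulate_snp_matrix(
    panel: Sequence[AccessionProfile],
    config: PanelConfig | None = None,
    seed: int = 0,
    flanks: tuple[GenomicInterval, GenomicInterval] = SNP_FLANKS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bi-allelic SNP matrix over the two flanking windows, plus truth.

    Returns ``(matrix, site_truth)``: the matrix has one row per position
    (index ``chrom:pos``), one column per accession, values in
    {ref base, alt base, 'N'}.  Alleles are drawn independently of the
    CNV pattern (per-site MAF from the configured uniform range), so any
    SNP–CNV correlation is sampling noise.  ``ld_rho`` > 0 makes each
    site copy its left neighbour's haplotype with that probability,
    creating local LD blocks.
    """
    config = config or PanelConfig()
    rng = np.random.default_rng(seed)
    n_sites = config.n_snps
    half = n_sites // 2
    counts = (half, n_sites - half)
    positions = []
    for flank, cnt in zip(flanks, counts):
        pos = np.sort(rng.choice(
            np.arange(flank.start, flank.end + 1), size=cnt, replace=False
        ))
        positions.extend((flank.chrom, int(p)) for p in pos)

    acc_ids = [p.accession_id for p in panel]
    n_acc = len(acc_ids)
    mafs = rng.uniform(config.maf_min, config.maf_max, size=len(positions))
    data = np.empty((len(positions), n_acc), dtype="<U1")
    refs, alts = [], []
    prev = None
    for i, (chrom, pos) in enumerate(positions):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        refs.append(ref)
        alts.append(alt)
        hap = rng.random(n_acc) < mafs[i]  # True = alt allele (haploid)
        if prev is not None and rng.random() < config.ld_rho:
            hap = prev.copy()
        prev = hap
        row = np.where(hap, alt, ref)
        missing = rng.random(n_acc) < config.snp_missing_rate
        row[missing] = "N"
        data[i] = row
    index = [f"{chrom}:{pos}" for chrom, pos in positions]
    matrix = pd.DataFrame(data, index=index, columns=acc_ids)
    matrix.index.name = "position"
    truth = pd.DataFrame(
        {"ref": refs, "alt": alts, "maf": mafs}, index=index
    )
    truth.index.name = "position"
    return matrix, truth
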