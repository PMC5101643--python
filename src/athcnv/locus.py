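"""Locus geometry: coordinates, the LCR pair, and NAHR arithmetic.

Coordinates are 1-based, fully closed intervals (``Chr3:6372413..6373650``
style), the convention used for plant genome annotation.  Writers that emit
BED convert to 0-based half-open; GFF3 output stays 1-based.

The locus modelled here is a ~25.5-kb chromosome 3 segment carrying (left
to right on the plus strand) HDA15, MSH2, the left LCR, AT3G18530,
AT3G18535, the right LCR and BRC1.  The two 1238-bp low-copy repeats (LCRs)
are direct repeats of ~99% identity differing at 11 paralogous sequence
variants (PSVs); recombination between them (NAHR) removes or duplicates
one repeat plus the intervening two-gene block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "GenomicInterval",
    "LcrPair",
    "LocusMap",
    "interval_length",
    "nahr_deletion_size",
    "predict_junction_amplicon",
    "homology_tracks",
    "psv_intervals",
    "default_locus_map",
    "DEFAULT_PSV_OFFSETS",
]

# Offsets 231 and 769 delimit the two long perfect-homology tracks in the
# 5' half of the alignment; the remaining nine variant sites cluster in the
# 3' half and are placed at even spacing (overridable in LcrPair).
DEFAULT_PSV_OFFSETS: tuple[int, ...] = (
    231, 769, 810, 860, 910, 960, 1010, 1060, 1110, 1160, 1210,
)
_DEFAULT_LEFT_ALLELES = "TACGTACGTAC"
_DEFAULT_RIGHT_ALLELES = "AGTACGTACGT"


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # Chr3:6372413..6373650 notation
        return f"{self.chrom}:{self.start}..{self.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a closed interval (``end − start + 1``)."""
    return iv.end - iv.start + 1


@dataclass(frozen=True)
class LcrPair:
    """A pair of direct low-copy repeats and the PSVs that tell them apart.

    ``psv_positions`` are 1-based offsets within the repeat alignment; at
    each such offset the left and right copy carry different bases
    (``left_alleles`` / ``right_alleles``), so a recombinant junction can be
    painted base-by-base as left-derived or right-derived.
    """

    left: GenomicInterval
    right: GenomicInterval
    alignment_length: int = 1238
    psv_positions: tuple[int, ...] = DEFAULT_PSV_OFFSETS
    left_alleles: str = _DEFAULT_LEFT_ALLELES
    right_alleles: str = _DEFAULT_RIGHT_ALLELES
    # Optional backbone: the left-copy sequence of the alignment.  Needed
    # only for sequence-level work (junction painting); geometry does not
    # require it.
    alignment_seq: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "psv_positions", tuple(self.psv_positions))
        if self.left.chrom != self.right.chrom:
            raise ValueError("LCR copies must lie on the same chromosome")
        if self.left.end >= self.right.start:
            raise ValueError(
                "LCR copies must be non-overlapping direct repeats "
                f"(left ends {self.left.end}, right starts {self.right.start})"
            )
        if interval_length(self.left) != self.alignment_length:
            raise ValueError("left LCR length != alignment_length")
        if interval_length(self.right) != self.alignment_length:
            raise ValueError("right LCR length != alignment_length")
        n = len(self.psv_positions)
        if not (n == len(self.left_alleles) == len(self.right_alleles)):
            raise ValueError("PSV positions and allele strings must align")
        if list(self.psv_positions) != sorted(set(self.psv_positions)):
            raise ValueError("PSV positions must be sorted and unique")
        for p in self.psv_positions:
            if not 1 <= p <= self.alignment_length:
                raise ValueError(f"PSV offset {p} outside alignment")
        for i, (a, b) in enumerate(zip(self.left_alleles, self.right_alleles)):
            if a == b:
                raise ValueError(
                    f"PSV {i + 1}: left and right alleles must differ"
                )
        if self.alignment_seq is not None:
            if len(self.alignment_seq) != self.alignment_length:
                raise ValueError("alignment_seq length != alignment_length")
            for p, a in zip(self.psv_positions, self.left_alleles):
                if self.alignment_seq[p - 1] != a:
                    raise ValueError(
                        f"alignment_seq[{p}] must carry the left allele {a}"
                    )

    @property
    def n_psv(self) -> int:
        return len(self.psv_positions)

    def left_seq(self) -> str:
        """Sequence of the left repeat copy (the alignment backbone)."""
        if self.alignment_seq is None:
            raise ValueError("LcrPair carries no backbone sequence")
        return self.alignment_seq

    def right_seq(self) -> str:
        """Sequence of the right repeat copy (backbone with right alleles)."""
        seq = list(self.left_seq())
        for p, a in zip(self.psv_positions, self.right_alleles):
            seq[p - 1] = a
        return "".join(seq)


def nahr_deletion_size(lcr: LcrPair) -> int:
    """Length of sequence removed by NAHR between the two repeats.

    When the repeats recombine into a single copy, the genome loses one
    repeat plus everything between the copies: ``right.start − left.start``.
    """
    size = lcr.right.start - lcr.left.start
    if size <= 0:
        raise ValueError("repeats overlap or coincide; NAHR size undefined")
    return size


def homology_tracks(lcr: LcrPair) -> list[tuple[int, int, int]]:
    """Maximal runs of positions identical between the two repeat copies.

    Returns ``(start_offset, end_offset, length)`` triples covering the
    gaps between consecutive PSVs and the alignment ends.  Lengths sum to
    ``alignment_length − n_psv``.
    """
    tracks: list[tuple[int, int, int]] = []
    prev = 0  # offset of the previous PSV (0 = before alignment start)
    for p in lcr.psv_positions:
        if p - prev > 1:
            tracks.append((prev + 1, p - 1, p - prev - 1))
        prev = p
    if lcr.alignment_length - prev >= 1:
        tracks.append(
            (prev + 1, lcr.alignment_length, lcr.alignment_length - prev)
        )
    return tracks


def psv_intervals(lcr: LcrPair) -> list[tuple[int, int]]:
    """Breakpoint-localization bins delimited by PSVs and alignment ends.

    Interval 1 runs from alignment position 1 to the first PSV, interval 2
    between the first and second PSV, and so on; a strand exchange inside
    bin *i* cannot be localized more finely than its two bounds.
    """
    bounds = [1, *lcr.psv_positions, lcr.alignment_length]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


@dataclass(frozen=True)
class LocusMap:
    """Coordinate map of the assayed segment.

    ``primer_anchors`` holds the positions of the deletion-junction primer
    pair (outside the LCRs); ``dup_junction_amplicon_bp`` is the measured
    length of the tail-to-head duplication junction amplicon, kept as a map
    constant because the duplication primers sit inside sequence that only
    exists in rearranged genomes.
    """

    region: GenomicInterval
    genes: dict[str, GenomicInterval]
    lcr: LcrPair
    probe_targets: dict[str, GenomicInterval] = field(default_factory=dict)
    primer_anchors: dict[str, int] = field(default_factory=dict)
    dup_junction_amplicon_bp: int = 3404

    _REQUIRED_GENES = ("HDA15", "MSH2", "AT3G18530", "AT3G18535", "BRC1")
    _REQUIRED_PROBES = tuple(f"mlpa{c}" for c in "ABCDEFGH")

    def __post_init__(self) -> None:
        for name in self._REQUIRED_GENES:
            if name not in self.genes:
                raise ValueError(f"gene {name} missing from locus map")
        for name, iv in self.genes.items():
            if not self.region.contains(iv):
                raise ValueError(f"gene {name} outside region")
        for name, iv in self.probe_targets.items():
            if not self.region.contains(iv):
                raise ValueError(f"probe target {name} outside region")
        if self.probe_targets:
            missing = set(self._REQUIRED_PROBES) - set(self.probe_targets)
            if missing:
                raise ValueError(f"probe targets missing: {sorted(missing)}")
        lcr = self.lcr
        if not (self.region.contains(lcr.left) and self.region.contains(lcr.right)):
            raise ValueError("LCR copies must lie within the region")
        for name in ("AT3G18530", "AT3G18535"):
            g = self.genes[name]
            if not (lcr.left.end < g.start and g.end < lcr.right.start):
                raise ValueError(f"{name} must lie strictly between the LCRs")
        if self.genes["MSH2"].start >= lcr.left.start:
            raise ValueError("MSH2 must lie left of the left LCR")

    @property
    def block_region(self) -> GenomicInterval:
        """The deletable AT3G18530–AT3G18535 block between the two repeats."""
        return GenomicInterval(
            self.region.chrom, self.lcr.left.end + 1, self.lcr.right.start - 1
        )

    @property
    def deleted_span(self) -> GenomicInterval:
        """Sequence removed by the NAHR deletion (one LCR plus the block)."""
        return GenomicInterval(
            self.region.chrom, self.lcr.left.start, self.lcr.right.start - 1
        )

    def reference_deletion_amplicon_bp(self) -> int:
        f = self.primer_anchors["del_forward"]
        r = self.primer_anchors["del_reverse"]
        return r - f + 1

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        iv = lambda x: {"chrom": x.chrom, "start": x.start, "end": x.end}
        return {
            "region": iv(self.region),
            "genes": {k: iv(v) for k, v in self.genes.items()},
            "lcr": {
                "left": iv(self.lcr.left),
                "right": iv(self.lcr.right),
                "alignment_length": self.lcr.alignment_length,
                "psv_positions": list(self.lcr.psv_positions),
                "left_alleles": self.lcr.left_alleles,
                "right_alleles": self.lcr.right_alleles,
                "alignment_seq": self.lcr.alignment_seq,
            },
            "probe_targets": {k: iv(v) for k, v in self.probe_targets.items()},
            "primer_anchors": dict(self.primer_anchors),
            "dup_junction_amplicon_bp": self.dup_junction_amplicon_bp,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "LocusMap":
        iv = lambda x: GenomicInterval(x["chrom"], x["start"], x["end"])
        lcr = LcrPair(
            left=iv(d["lcr"]["left"]),
            right=iv(d["lcr"]["right"]),
            alignment_length=d["lcr"]["alignment_length"],
            psv_positions=tuple(d["lcr"]["psv_positions"]),
            left_alleles=d["lcr"]["left_alleles"],
            right_alleles=d["lcr"]["right_alleles"],
            alignment_seq=d["lcr"].get("alignment_seq"),
        )
        return cls(
            region=iv(d["region"]),
            genes={k: iv(v) for k, v in d["genes"].items()},
            lcr=lcr,
            probe_targets={k: iv(v) for k, v in d["probe_targets"].items()},
            primer_anchors=dict(d["primer_anchors"]),
            dup_junction_amplicon_bp=d["dup_junction_amplicon_bp"],
        )

    @classmethod
    def from_json(cls, source) -> "LocusMap":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def _features(self):
        yield "region", "region", self.region
        for name, g in sorted(self.genes.items()):
            yield name, "gene", g
        yield "LCR_left", "repeat", self.lcr.left
        yield "LCR_right", "repeat", self.lcr.right
        for name, p in sorted(self.probe_targets.items()):
            yield name, "probe", p

    def to_bed(self, path=None) -> str:
        """BED export; 1-based closed intervals become 0-based half-open."""
        lines = [
            f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}"
            for name, _kind, iv in self._features()
        ]
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_gff3(self, path=None) -> str:
        lines = ["##gff-version 3"]
        for name, kind, iv in self._features():
            gff_type = {"gene": "gene", "repeat": "repeat_region"}.get(
                kind, "region"
            )
            lines.append(
                f"{iv.chrom}\tathcnv\t{gff_type}\t{iv.start}\t{iv.end}"
                f"\t.\t+\t.\tID={name}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def predict_junction_amplicon(
    locus: LocusMap,
    genotype_pattern: str,
    reference_amplicon_bp: int | None = None,
    duplication_extension_bp: int = 0,
    primer_pair: str | None = None,
) -> int | None:
    """Predict the breakpoint-spanning PCR product length for a genotype.

    The deletion primer pair flanks the whole LCR–block–LCR span: a basic
    genome yields the full-length reference product, a deletion genome a
    product shorter by exactly the NAHR-deleted segment.  The duplication
    primer pair points outward across the internal tail-to-head junction,
    so it yields a product only when a tandem duplication exists
    (``None`` = no product on a basic genome); extended duplications add
    ``duplication_extension_bp``.
    """
    known = {"basic", "del-2", "dupl-2", "dupl-2-extended"}
    if genotype_pattern not in known:
        raise ValueError(f"unknown genotype pattern: {genotype_pattern!r}")

    if primer_pair is None:
        primer_pair = (
            "duplication"
            if genotype_pattern in ("dupl-2", "dupl-2-extended")
            else "deletion"
        )
    if primer_pair not in ("deletion", "duplication"):
        raise ValueError(f"unknown primer pair: {primer_pair!r}")

    if primer_pair == "deletion":
        if reference_amplicon_bp is None:
            reference_amplicon_bp = locus.reference_deletion_amplicon_bp()
        if genotype_pattern == "basic":
            return reference_amplicon_bp
        if genotype_pattern == "del-2":
            return reference_amplicon_bp - nahr_deletion_size(locus.lcr)
        raise ValueError(
            "deletion primer pair is uninformative for duplication genotypes"
        )

    # duplication primer pair
    if genotype_pattern == "basic":
        return None  # junction template absent: no product
    if genotype_pattern == "del-2":
        return None
    base = locus.dup_junction_amplicon_bp
    if genotype_pattern == "dupl-2-extended":
        return base + duplication_extension_bp
    return base + duplication_extension_bp


def default_locus_map(chrom: str = "Chr3") -> LocusMap:
    """The default locus map with the published repeat coordinates.

    LCR copies sit at Chr3:6372413..6373650 and Chr3:6377368..6378605;
    gene bodies and probe targets use synthetic but invariant-respecting
    coordinates inside a 25.5-kb region, and the deletion primer anchors
    are placed so the no-deletion amplicon is 8376 bp.
    """
    lcr = LcrPair(
        left=GenomicInterval(chrom, 6372413, 6373650),
        right=GenomicInterval(chrom, 6377368, 6378605),
    )
    genes = {
        "HDA15": GenomicInterval(chrom, 6356000, 6359200),
        "MSH2": GenomicInterval(chrom, 6367200, 6372400),
        "AT3G18530": GenomicInterval(chrom, 6373700, 6375900),
        "AT3G18535": GenomicInterval(chrom, 6376200, 6377200),
        "BRC1": GenomicInterval(chrom, 6379000, 6380200),
    }
    probes = {
        "mlpaA": GenomicInterval(chrom, 6357000, 6357059),
        "mlpaB": GenomicInterval(chrom, 6368000, 6368059),
        "mlpaC": GenomicInterval(chrom, 6371500, 6371559),
        "mlpaD": GenomicInterval(chrom, 6373800, 6373859),
        "mlpaE": GenomicInterval(chrom, 6375000, 6375059),
        "mlpaF": GenomicInterval(chrom, 6376300, 6376359),
        "mlpaG": GenomicInterval(chrom, 6377000, 6377059),
        "mlpaH": GenomicInterval(chrom, 6379500, 6379559),
    }
    anchors = {"del_forward": 6371000, "del_reverse": 6379375}
    return LocusMap(
        region=GenomicInterval(chrom, 6355000, 6380499),
        genes=genes,
        lcr=lcr,
        probe_targets=probes,
        primer_anchors=anchors,
    )
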