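"""Shared I/O: FASTA reading/writing and run configuration.

FASTA handling is a thin layer over Biopython's ``SeqIO`` with strict
validation: sequences are normalized to uppercase (with a note returned
when lowercase was present) and restricted to IUPAC DNA plus N; malformed
input raises :class:`FastaError` carrying the offending line number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from io import StringIO

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from athcnv.simulate import PanelConfig

__all__ = [
    "FastaError",
    "read_fasta",
    "write_fasta",
    "RunConfig",
]

_VALID_CHARS = set("ACGTURYSWKMBDHVN")


class FastaError(ValueError):
    """Malformed FASTA input; message carries the line number."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercase sequence)`` pairs.

    Empty files yield an empty list.  A file whose first non-blank line
    is not a header, or any sequence character outside IUPAC DNA + N,
    raises :class:`FastaError` with the line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    line_no_of_first_content = None
    for i, line in enumerate(lines, start=1):
        if line.strip():
            line_no_of_first_content = i
            break
    if line_no_of_first_content is None:
        return []
    if not lines[line_no_of_first_content - 1].startswith(">"):
        raise FastaError(
            f"line {line_no_of_first_content}: expected FASTA header '>'"
        )
    # validate characters line by line so errors carry positions
    for i, line in enumerate(lines, start=1):
        if line.startswith(">") or not line.strip():
            continue
        bad = set(line.strip().upper()) - _VALID_CHARS
        if bad:
            raise FastaError(
                f"line {i}: invalid sequence characters {sorted(bad)}"
            )
    records = []
    for rec in SeqIO.parse(StringIO("".join(lines)), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(path, records, width: int = 80) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Defaults reproduce the demonstration panel (189 accessions with the
    study-like genotype mix).  Unknown keys in a config file are
    rejected.  One master seed drives every stage through deterministic
    substreams, so stages can be re-run independently.
    """

    seed: int = 0
    panel: PanelConfig = field(default_factory=PanelConfig)
    # stage toggles
    run_mlpa: bool = True
    run_ddpcr: bool = True
    run_breakpoints: bool = True
    run_popstats: bool = True
    # analysis parameters
    calibrator_id: str = "Col-0"
    mlpa_del_threshold: float = 0.5
    mlpa_dup_threshold: float = 1.5
    dupl3b_factor: float = 1.5
    ddpcr_reference: str = "DCL1"
    min_maf: float = 0.10
    max_missing: float = 0.20
    del2_missingness_threshold: float = 0.80

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        panel_d = d.pop("panel", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        panel_known = {f.name for f in dataclasses.fields(PanelConfig)}
        unknown_p = set(panel_d) - panel_known
        if unknown_p:
            raise ValueError(f"unknown panel config keys: {sorted(unknown_p)}")
        return cls(panel=PanelConfig(**panel_d), **d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
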