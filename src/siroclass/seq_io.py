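"""FASTA ingest/egress, run configuration, and tabular output.

Protein records are plain named sequences over the 20 amino-acid letters
plus ``X``. Residue coordinates are 1-based and inclusive everywhere in
this package. FASTA headers follow the common dialect: the first
whitespace-delimited token is the record id, an optional bracketed suffix
(``[Methanocaldococcus jannaschii]``) is parsed as the organism, and
round-tripping a file through :func:`read_fasta`/:func:`write_fasta`
preserves sequence content byte-identically (headers are normalized).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaError, SiroclassError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_VALID = set(ALPHABET)
_ORGANISM_RE = re.compile(r"\[([^\[\]]*)\]\s*$")


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One named amino-acid sequence with an optional organism tag."""

    id: str
    sequence: str
    organism: str = ""

    def __post_init__(self):
        if not self.id:
            raise FastaError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise FastaError(f"record '{self.id}': sequence must be non-empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _VALID:
                raise FastaError(
                    f"record '{self.id}': invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord`s.

    The first header token becomes the id; a trailing ``[...]`` in the
    description becomes the organism. Sequences are uppercased on ingest.
    Raises :class:`FastaError` on an empty file, duplicate ids, or residues
    outside the 20 amino acids + ``X``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            header = header.strip()
            if not header:
                raise FastaError(f"{path}: empty FASTA header")
            tokens = header.split(None, 1)
            rid = tokens[0]
            description = tokens[1] if len(tokens) > 1 else ""
            m = _ORGANISM_RE.search(description)
            organism = m.group(1).strip() if m else ""
            if rid in seen:
                raise FastaError(f"{path}: duplicate record id '{rid}'")
            seen.add(rid)
            records.append(ProteinRecord(rid, seq.upper().replace(" ", ""), organism))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records with normalized ``>id [organism]`` headers."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id} [{rec.organism}]" if rec.organism else f">{rec.id}"
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


@dataclasses.dataclass
class RunConfig:
    """Thresholds, scoring parameters and the single seed driving a run.

    All randomness in a pipeline run (bootstrap resampling, any simulation)
    derives deterministically from ``seed``, which is recorded in every
    output for reproducibility.
    """

    anchor_profile_path: str | None = None  # None -> packaged default profile
    min_core_score: float = 0.5
    gap_open: float = -11.0
    gap_extend: float = -1.0
    max_gap_fraction: float = 0.5
    bootstrap_n: int = 100
    seed: int = 0
    siroheme_min_anchors: int = 4
    peripheral_min_anchors: int = 4

    def __post_init__(self):
        if not (0.0 <= self.max_gap_fraction <= 1.0):
            raise SiroclassError("max_gap_fraction must lie in [0, 1]")
        if not (0.0 <= self.min_core_score <= 1.0):
            raise SiroclassError("min_core_score must lie in [0, 1]")
        if self.bootstrap_n < 1:
            raise SiroclassError("bootstrap_n must be a positive integer")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise SiroclassError("require gap_open <= gap_extend <= 0")
        for name in ("siroheme_min_anchors", "peripheral_min_anchors"):
            v = getattr(self, name)
            if not (1 <= v <= 4):
                raise SiroclassError(f"{name} must lie in 1..4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SiroclassError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Deterministic column order for the per-protein signature/label table.
FEATURE_TABLE_COLUMNS = [
    "id",
    "organism",
    "siroheme_site",
    "peripheral_cluster",
    "additional_cluster",
    "sb_pattern",
    "frh_core",
    "ferredoxin_n_count",
    "ferredoxin_c_count",
    "fusion_order_ok",
    "family",
    "group",
    "subgroup",
    "arch_class",
    "sublabel",
    "flags",
]


def feature_table_frame(records, feature_vectors, labels) -> pd.DataFrame:
    """Assemble the per-protein table of signatures and labels.

    One row per protein: presence bits for the siroheme site, peripheral (*)
    and additional (**) clusters, the sulfite-binding residue pattern as a
    4-character string (e.g. ``1011`` = SB2 missing), FrhB-core and
    ferredoxin-extension summaries, and the classification outcome.
    """
    records = list(records)
    feature_vectors = list(feature_vectors)
    labels = list(labels)
    if not (len(records) == len(feature_vectors) == len(labels)):
        raise SiroclassError(
            "records, feature_vectors and labels must have equal length "
            f"(got {len(records)}, {len(feature_vectors)}, {len(labels)})"
        )
    rows = []
    for rec, fv, lab in zip(records, feature_vectors, labels):
        rows.append(
            {
                "id": rec.id,
                "organism": rec.organism,
                "siroheme_site": int(fv.siroheme_site),
                "peripheral_cluster": int(fv.peripheral_cluster),
                "additional_cluster": int(fv.additional_cluster),
                "sb_pattern": fv.sb_pattern,
                "frh_core": int(fv.frh_core),
                "ferredoxin_n_count": fv.ferredoxin_n_count,
                "ferredoxin_c_count": fv.ferredoxin_c_count,
                "fusion_order_ok": int(fv.fusion_order_ok),
                "family": lab.family,
                "group": lab.group or "",
                "subgroup": lab.subgroup or "",
                "arch_class": lab.arch_class or "",
                "sublabel": lab.sublabel or "",
                "flags": ",".join(sorted(lab.flags)),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def write_feature_table(records, feature_vectors, labels, path: str | Path) -> None:
    """Write the signature/label table as TSV (header-only when empty)."""
    frame = feature_table_frame(records, feature_vectors, labels)
    frame.to_csv(path, sep="\t", index=False)


def read_context_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping protein id -> genomic-context tag."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["id", "tag"], dtype=str)
    return dict(zip(frame["id"], frame["tag"]))
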