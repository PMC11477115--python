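"""Reading, filtering and writing coding sequences.

A chloroplast CDS enters the analysis only if it looks like a clean,
translatable gene: ATG start, a genuine terminal stop (TAA/TAG/TGA), no
internal in-frame stop, length a multiple of three and at least ``min_len``
nucleotides (300 by default), and unambiguous bases.  Inverted-repeat
duplicates are collapsed by gene name (first occurrence kept) unless
deduplication is switched off.
"""

from __future__ import annotations

import collections
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence
import warnings

from Bio import SeqIO

from .genetics import STOP_CODONS

VALID_BASES = frozenset("ACGT")

#: rejection reason codes, in the order checks are applied
REASONS = (
    "ambiguous_base",
    "frame",
    "length",
    "start",
    "stop",
    "internal_stop",
    "duplicate",
)


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame nucleotide CDS with identity and species labels."""

    id: str
    species: str
    seq: str

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass
class CdsSet:
    """An ordered, uniquely-identified collection of CDSs from one species."""

    species: str
    members: list[CodingSequence]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for m in self.members:
            if m.species != self.species:
                raise ValueError(
                    f"member {m.id!r} carries species {m.species!r}, "
                    f"set is {self.species!r}"
                )
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            dup = [i for i, n in collections.Counter(ids).items() if n > 1]
            raise ValueError(f"duplicate ids within set: {dup}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.members)


@dataclass
class FilterReport:
    """Outcome of CDS filtering: per-gene status and aggregate counts."""

    accepted: int = 0
    rejected: int = 0
    reasons: dict[str, str] = field(default_factory=dict)  # gene id -> reason

    @property
    def reason_counts(self) -> dict[str, int]:
        counts = collections.Counter(self.reasons.values())
        return {r: counts.get(r, 0) for r in REASONS if counts.get(r, 0)}

    def to_rows(self, accepted_ids: Iterable[str]) -> list[tuple[str, str, str]]:
        rows = [(gid, "accepted", "") for gid in accepted_ids]
        rows += [(gid, "rejected", reason) for gid, reason in self.reasons.items()]
        return rows


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_cds(
    path: str | os.PathLike,
    format: str | None = None,
    species: str | None = None,
) -> list[CodingSequence]:
    """Read candidate CDSs from a GenBank flat file or a FASTA file.

    GenBank: one record per CDS feature, spliced and strand-resolved so the
    returned sequence reads 5'->3' in coding orientation.  FASTA: one record
    per entry; a ``species=<label>`` token in the description is honoured.
    Sequences are uppercased and RNA ``U`` is mapped to ``T``.
    """
    path = Path(path)
    if format is None:
        format = (
            "genbank"
            if path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"}
            else "fasta"
        )
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")

    out: list[CodingSequence] = []
    if format == "genbank":
        for record in SeqIO.parse(str(path), "genbank"):
            organism = species or record.annotations.get("organism", record.id)
            features = [f for f in record.features if f.type == "CDS"]
            if not features:
                warnings.warn(f"{path}: record {record.id} has no CDS features")
            seen: collections.Counter[str] = collections.Counter()
            for i, feat in enumerate(features):
                quals = feat.qualifiers
                name = (
                    quals.get("gene", quals.get("locus_tag", [None]))[0]
                    or f"{record.id}_cds{i + 1}"
                )
                seen[name] += 1
                if seen[name] > 1:
                    name = f"{name}_{seen[name]}"
                seq = _normalize(str(feat.extract(record.seq)))
                out.append(CodingSequence(id=name, species=organism, seq=seq))
    else:
        for record in SeqIO.parse(str(path), "fasta"):
            label = species
            if label is None:
                for token in record.description.split():
                    if token.startswith("species="):
                        label = token[len("species=") :]
                        break
            if label is None:
                label = path.stem
            out.append(
                CodingSequence(
                    id=record.id, species=label, seq=_normalize(str(record.seq))
                )
            )
    return out


def _rejection_reason(seq: str, min_len: int) -> str | None:
    if set(seq) - VALID_BASES:
        return "ambiguous_base"
    if len(seq) % 3 != 0:
        return "frame"
    if len(seq) < min_len:
        return "length"
    if not seq.startswith("ATG"):
        return "start"
    if seq[-3:] not in STOP_CODONS:
        return "stop"
    internal = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    if any(c in STOP_CODONS for c in internal):
        return "internal_stop"
    return None


def filter_cds(
    candidates: Sequence[CodingSequence],
    min_len: int = 300,
    dedupe: bool = True,
    provenance: tuple[str, ...] = (),
) -> tuple[CdsSet, FilterReport]:
    """Apply the five structural filtering rules plus deduplication.

    Retained genes start with ATG, end with TAA/TAG/TGA, contain no internal
    in-frame stop, have length divisible by 3 and >= ``min_len``, and use
    only A/C/G/T.  With ``dedupe`` the first occurrence of each gene id wins
    (inverted-repeat copies); later copies are rejected as ``duplicate``.
    """
    report = FilterReport()
    kept: list[CodingSequence] = []
    seen_ids: collections.Counter[str] = collections.Counter()
    species = candidates[0].species if candidates else "empty"
    for cand in candidates:
        reason = _rejection_reason(cand.seq, min_len)
        if reason is None and dedupe and seen_ids[cand.id]:
            reason = "duplicate"
        if reason is None:
            seen_ids[cand.id] += 1
            if seen_ids[cand.id] > 1:  # dedupe off: keep, but ids stay unique
                cand = CodingSequence(
                    id=f"{cand.id}_copy{seen_ids[cand.id]}",
                    species=cand.species,
                    seq=cand.seq,
                )
            kept.append(cand)
            report.accepted += 1
        else:
            key = cand.id
            while key in report.reasons:  # duplicates may share an id
                key += "+"
            report.reasons[key] = reason
            report.rejected += 1
    return CdsSet(species=species, members=kept, provenance=provenance), report


def write_cds_fasta(cds_set: CdsSet, path: str | os.PathLike) -> Path:
    """Write a CdsSet as 60-column FASTA with ``>id species=<species>`` headers."""
    if not cds_set.members:
        raise ValueError("refusing to write an empty CdsSet")
    path = Path(path)
    with open(path, "w") as fh:
        for gene in cds_set:
            fh.write(f">{gene.id} species={gene.species}\n")
            for i in range(0, len(gene.seq), 60):
                fh.write(gene.seq[i : i + 60] + "\n")
    return path


def write_filter_report(
    report: FilterReport, accepted_ids: Iterable[str], path: str | os.PathLike
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tstatus\treason\n")
        for gid, status, reason in report.to_rows(accepted_ids):
            fh.write(f"{gid}\t{status}\t{reason}\n")
    return path
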