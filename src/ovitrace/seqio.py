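"""Alignment and metadata I/O, haplotype collapsing and subsampling.

Sequences arrive already aligned (equal length, gap characters allowed);
this module validates them, attaches per-sequence metadata (breed, region,
optional haplogroup) and provides the site-filtering, haplotype-collapsing
and subsampling primitives every downstream analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTN-")
#: characters treated as missing data when filtering columns
MISSING_CHARS = frozenset("N-")


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants."""


class MetadataError(ValueError):
    """Raised when the metadata table does not match the alignment."""


@dataclass
class Alignment:
    """An aligned set of nucleotide sequences with optional metadata.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, one per row.
    seqs:
        Upper-case strings over ``{A,C,G,T,N,-}``, all of equal length.
    metadata:
        Optional mapping ``id -> {"breed": ..., "region": ..., "haplogroup": ...}``.
        When supplied it must cover every sequence id.
    """

    ids: list[str]
    seqs: list[str]
    metadata: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if self.seqs:
            L = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise AlignmentError(
                        f"sequence {sid!r} has length {len(s)}, expected {L}"
                    )
                bad = set(s) - VALID_CHARS
                if bad:
                    raise AlignmentError(
                        f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                    )
        if self.metadata is not None:
            missing = [i for i in self.ids if i not in self.metadata]
            if missing:
                raise MetadataError(f"ids missing from metadata: {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single-byte strings."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype="S1"
        ).reshape(self.n, self.length)

    def restrict(self, sites: Sequence[int]) -> "Alignment":
        """New alignment keeping only the given 0-based columns."""
        sites = list(sites)
        seqs = ["".join(s[j] for j in sites) for s in self.seqs]
        return Alignment(list(self.ids), seqs, self.metadata)

    def take(self, indices: Sequence[int]) -> "Alignment":
        """New alignment keeping only the given sequence rows."""
        ids = [self.ids[i] for i in indices]
        seqs = [self.seqs[i] for i in indices]
        meta = None
        if self.metadata is not None:
            meta = {i: self.metadata[i] for i in ids}
        return Alignment(ids, seqs, meta)

    def by_breed(self) -> dict[str, "Alignment"]:
        """Split into per-breed sub-alignments (requires metadata)."""
        if self.metadata is None:
            raise MetadataError("metadata required to split by breed")
        out: dict[str, Alignment] = {}
        breeds = sorted({self.metadata[i]["breed"] for i in self.ids})
        for b in breeds:
            idx = [k for k, i in enumerate(self.ids) if self.metadata[i]["breed"] == b]
            out[b] = self.take(idx)
        return out


@dataclass
class HaplotypeTable:
    """Distinct sequences with multiplicities and member ids."""

    haplotypes: list[tuple[str, int, list[str]]]
    n: int = field(default=0)

    def __post_init__(self) -> None:
        total = sum(c for _, c, _ in self.haplotypes)
        if self.n == 0:
            self.n = total
        if total != self.n:
            raise ValueError("haplotype counts do not sum to n")
        seqs = [h for h, _, _ in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences are not distinct")

    @property
    def H(self) -> int:
        """Number of distinct haplotypes."""
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [c for _, c, _ in self.haplotypes]


def read_metadata(path: str) -> dict[str, dict[str, str]]:
    """Read a tab-separated metadata table (columns id, breed, region[, haplogroup])."""
    meta: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        lower = [h.strip().lower() for h in header]
        for col in ("id", "breed", "region"):
            if col not in lower:
                raise MetadataError(f"metadata missing required column {col!r}")
        idx = {c: lower.index(c) for c in lower}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            row = {c: (parts[i] if i < len(parts) else "") for c, i in idx.items()}
            sid = row["id"]
            if sid in meta:
                raise MetadataError(f"duplicate id in metadata: {sid!r}")
            meta[sid] = {
                "breed": row["breed"],
                "region": row["region"],
                "haplogroup": row.get("haplogroup", ""),
            }
    return meta


def read_alignment(fasta_path: str, metadata_path: str | None = None) -> Alignment:
    """Read an aligned FASTA plus optional TSV metadata into an :class:`Alignment`.

    Sequences are upper-cased on read; characters outside ``{A,C,G,T,N,-}``
    are rejected.  When metadata is supplied every sequence id must appear
    in it.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no sequences found in {fasta_path!r}")
    meta = read_metadata(metadata_path) if metadata_path else None
    return Alignment(ids, seqs, meta)


def write_alignment(a: Alignment, fasta_path: str, metadata_path: str | None = None) -> None:
    """Write FASTA (and, if requested, the TSV metadata) back to disk."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.seqs)
    ]
    SeqIO.write(records, fasta_path, "fasta")
    if metadata_path is not None:
        if a.metadata is None:
            raise MetadataError("alignment carries no metadata to write")
        with open(metadata_path, "w", encoding="utf-8") as fh:
            fh.write("id\tbreed\tregion\thaplogroup\n")
            for i in a.ids:
                m = a.metadata[i]
                fh.write(
                    f"{i}\t{m.get('breed', '')}\t{m.get('region', '')}\t"
                    f"{m.get('haplogroup', '')}\n"
                )


def usable_sites(
    a: Alignment, policy: str = "complete", threshold: float = 0.95
) -> list[int]:
    """Return the 0-based columns retained under the given missing-data policy.

    ``complete`` drops any column containing a gap or ``N``; ``partial``
    keeps columns where at least ``threshold`` of sequences carry a real
    base (the 95% presence convention used when building trees from
    control-region alignments).
    """
    if policy not in ("complete", "partial"):
        raise ValueError(f"unknown site policy {policy!r}")
    M = a.matrix()
    present = ~np.isin(M, [b"N", b"-"])
    if policy == "complete":
        keep = present.all(axis=0)
    else:
        keep = present.mean(axis=0) >= threshold
    sites = np.flatnonzero(keep).tolist()
    if not sites:
        raise AlignmentError("no columns retained under the site policy")
    return sites


def collapse_haplotypes(a: Alignment, sites: Sequence[int] | None = None) -> HaplotypeTable:
    """Group identical sequences (restricted to ``sites``) into haplotypes.

    The table is ordered by decreasing multiplicity, ties broken by
    lexicographic sequence, so collapsing is invariant to input order.
    """
    if sites is None:
        sites = range(a.length)
    sites = list(sites)
    if not sites:
        raise ValueError("sites must be non-empty")
    groups: dict[str, list[str]] = {}
    for sid, s in zip(a.ids, a.seqs):
        key = "".join(s[j] for j in sites)
        groups.setdefault(key, []).append(sid)
    haps = [(seq, len(members), sorted(members)) for seq, members in groups.items()]
    haps.sort(key=lambda h: (-h[1], h[0]))
    return HaplotypeTable(haps, n=a.n)


def subsample(a: Alignment, n: int, seed: int) -> Alignment:
    """Uniform without-replacement subsample of ``n`` sequences.

    Mirrors the size-adjustment step used to put population samples on a
    common footing before computing diversity indices.  Reproducible for a
    fixed seed; original row order is preserved.
    """
    if n > a.n:
        raise ValueError(f"cannot subsample {n} from {a.n} sequences")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(a.n, size=n, replace=False))
    return a.take(idx.tolist())
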